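<?xml version="1.0" encoding="UTF-8"?>
<!-- Schema of the view control files: one anatomical view binding tissue
     groups (samples + external record) to key colours of a base image.
     Key colours must be painted flat (no anti-aliasing) in the image so
     region membership is an exact RGB match. -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">

  <xs:simpleType name="hexColour">
    <xs:restriction base="xs:string">
      <xs:pattern value="#[0-9A-Fa-f]{6}"/>
    </xs:restriction>
  </xs:simpleType>

  <xs:element name="view">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="group" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="sample" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
              <xs:element name="centroid" minOccurs="0">
                <xs:complexType>
                  <xs:attribute name="x" type="xs:nonNegativeInteger" use="required"/>
                  <xs:attribute name="y" type="xs:nonNegativeInteger" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="colour" type="hexColour" use="required"/>
            <xs:attribute name="record_id" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="name" type="xs:string" use="required"/>
      <xs:attribute name="platform" type="xs:string" use="required"/>
      <xs:attribute name="image" type="xs:string" use="required"/>
      <xs:attribute name="comparability_note" type="xs:string"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
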