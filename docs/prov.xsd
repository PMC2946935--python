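<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:element name="provenance">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="identity" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="field" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:simpleContent>
                    <xs:extension base="xs:string">
                      <xs:attribute name="name" type="xs:string" use="required"/>
                    </xs:extension>
                  </xs:simpleContent>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
        <xs:element name="steps" minOccurs="0">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="step" minOccurs="0" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="tool">
                      <xs:complexType>
                        <xs:attribute name="name" type="xs:string" use="required"/>
                        <xs:attribute name="version" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="executable">
                      <xs:complexType>
                        <xs:attribute name="path" type="xs:string" use="required"/>
                        <xs:attribute name="checksum" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="arguments">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="arg" type="xs:string"
                                      minOccurs="0" maxOccurs="unbounded"/>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="platform">
                      <xs:complexType>
                        <xs:attribute name="os" type="xs:string"/>
                        <xs:attribute name="arch" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="started" type="xs:string"/>
                    <xs:element name="ended" type="xs:string"/>
                    <xs:element name="inputs">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="file" minOccurs="0" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="id" type="xs:string" use="required"/>
                              <xs:attribute name="checksum" type="xs:string"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="outputs">
                      <xs:complexType>
                        <xs:sequence>
                          <xs:element name="file" minOccurs="0" maxOccurs="unbounded">
                            <xs:complexType>
                              <xs:attribute name="id" type="xs:string" use="required"/>
                            </xs:complexType>
                          </xs:element>
                        </xs:sequence>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="compilationFlags" type="xs:string" minOccurs="0"/>
                  </xs:sequence>
                  <xs:attribute name="index" type="xs:nonNegativeInteger"/>
                  <xs:attribute name="job" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="dataset" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
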