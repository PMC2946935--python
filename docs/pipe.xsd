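<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema" elementFormDefault="unqualified">

  <xs:element name="pipeline">
    <xs:complexType>
      <xs:choice minOccurs="0" maxOccurs="unbounded">
        <xs:element ref="variables"/>
        <xs:element ref="module"/>
        <xs:element ref="dataSource"/>
        <xs:element ref="studySource"/>
        <xs:element ref="conditional"/>
        <xs:element ref="loopGroup"/>
        <xs:element ref="repeatUntil"/>
        <xs:element ref="connection"/>
      </xs:choice>
      <xs:attribute name="id" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="variables">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="variable" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="item" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
            </xs:sequence>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="value" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

  <xs:element name="module">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="metadata" minOccurs="0">
          <xs:complexType>
            <xs:anyAttribute processContents="skip"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="environment" type="xs:string" minOccurs="0"/>
        <xs:element name="parameter" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="name" type="xs:string" use="required"/>
            <xs:attribute name="direction">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="input"/>
                  <xs:enumeration value="output"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
            <xs:attribute name="kind">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="file"/>
                  <xs:enumeration value="string"/>
                  <xs:enumeration value="number"/>
                  <xs:enumeration value="enumeration"/>
                  <xs:enumeration value="flag"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
            <xs:attribute name="format" type="xs:string"/>
            <xs:attribute name="dtype">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="byte"/>
                  <xs:enumeration value="short"/>
                  <xs:enumeration value="float"/>
                  <xs:enumeration value="none"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
            <xs:attribute name="cardinality" type="xs:string"/>
            <xs:attribute name="required" type="xs:string"/>
            <xs:attribute name="default" type="xs:string"/>
            <xs:attribute name="binding" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="label" type="xs:string"/>
      <xs:attribute name="executable" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="dataSource">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="item" type="xs:string" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="format" type="xs:string"/>
      <xs:attribute name="dtype" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="studySource">
    <xs:complexType>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="table" type="xs:string" use="required"/>
      <xs:attribute name="pathColumn" type="xs:string" use="required"/>
      <xs:attribute name="format" type="xs:string"/>
      <xs:attribute name="cohort" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="conditional">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="input" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="port" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="branch" minOccurs="2" maxOccurs="2">
          <xs:complexType>
            <xs:group ref="graphContent" minOccurs="0" maxOccurs="unbounded"/>
            <xs:attribute name="which" use="required">
              <xs:simpleType>
                <xs:restriction base="xs:string">
                  <xs:enumeration value="true"/>
                  <xs:enumeration value="false"/>
                </xs:restriction>
              </xs:simpleType>
            </xs:attribute>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="predicate" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="loopGroup">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="body">
          <xs:complexType>
            <xs:group ref="graphContent" minOccurs="0" maxOccurs="unbounded"/>
          </xs:complexType>
        </xs:element>
        <xs:element ref="export" minOccurs="0" maxOccurs="unbounded"/>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="iterationSource" type="xs:string" use="required"/>
      <xs:attribute name="iterationVar" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="repeatUntil">
    <xs:complexType>
      <xs:sequence>
        <xs:element ref="module"/>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string" use="required"/>
      <xs:attribute name="condition" type="xs:string" use="required"/>
      <xs:attribute name="maxIter" type="xs:positiveInteger"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="connection">
    <xs:complexType>
      <xs:attribute name="source" type="xs:string" use="required"/>
      <xs:attribute name="sourcePort" type="xs:string" use="required"/>
      <xs:attribute name="target" type="xs:string" use="required"/>
      <xs:attribute name="targetPort" type="xs:string" use="required"/>
      <xs:attribute name="smartline" type="xs:string"/>
    </xs:complexType>
  </xs:element>

  <xs:element name="export">
    <xs:complexType>
      <xs:attribute name="port" type="xs:string" use="required"/>
      <xs:attribute name="node" type="xs:string" use="required"/>
      <xs:attribute name="parameter" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:group name="graphContent">
    <xs:choice>
      <xs:element ref="variables"/>
      <xs:element ref="module"/>
      <xs:element ref="dataSource"/>
      <xs:element ref="studySource"/>
      <xs:element ref="conditional"/>
      <xs:element ref="loopGroup"/>
      <xs:element ref="connection"/>
      <xs:element ref="export"/>
    </xs:choice>
  </xs:group>

</xs:schema>
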