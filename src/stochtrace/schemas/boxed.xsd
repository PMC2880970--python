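<?xml version="1.0" encoding="UTF-8"?>
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           xmlns:bx="urn:stochtrace:boxed:1"
           targetNamespace="urn:stochtrace:boxed:1"
           elementFormDefault="qualified">

  <xs:element name="boxedModel">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="model" type="bx:ModelType"/>
        <xs:element name="traceGrid" type="bx:TraceGridType"/>
      </xs:sequence>
      <xs:attribute name="version" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

  <xs:complexType name="ModelType">
    <xs:sequence>
      <xs:element name="listOfSpecies">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="species" type="bx:SpeciesType"
                        minOccurs="0" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
      <xs:element name="listOfReactions">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="reaction" type="bx:ReactionType"
                        minOccurs="0" maxOccurs="unbounded"/>
          </xs:sequence>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
    <xs:attribute name="name" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="SpeciesType">
    <xs:sequence>
      <xs:element name="annotation" minOccurs="0" maxOccurs="unbounded">
        <xs:complexType>
          <xs:attribute name="dataType" type="xs:anyURI" use="required"/>
          <xs:attribute name="identifier" type="xs:string" use="required"/>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
    <xs:attribute name="id" type="bx:SId" use="required"/>
    <xs:attribute name="kind" use="required">
      <xs:simpleType>
        <xs:restriction base="xs:string">
          <xs:enumeration value="entity"/>
          <xs:enumeration value="complex"/>
          <xs:enumeration value="variable"/>
        </xs:restriction>
      </xs:simpleType>
    </xs:attribute>
    <xs:attribute name="initialAmount" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="ReactionType">
    <xs:sequence>
      <xs:element name="reactant" type="bx:SpeciesRefType"
                  minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="product" type="bx:SpeciesRefType"
                  minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="bx:SId" use="required"/>
    <xs:attribute name="type" type="xs:string" use="required"/>
    <xs:attribute name="rateConstant" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="SpeciesRefType">
    <xs:attribute name="species" type="bx:SId" use="required"/>
    <xs:attribute name="stoichiometry" type="xs:positiveInteger" default="1"/>
  </xs:complexType>

  <xs:complexType name="TraceGridType">
    <xs:sequence>
      <xs:element name="replica" minOccurs="1" maxOccurs="unbounded">
        <xs:complexType>
          <xs:sequence>
            <xs:element name="stream" type="bx:StreamType"
                        minOccurs="1" maxOccurs="unbounded"/>
          </xs:sequence>
          <xs:attribute name="seed" type="xs:long"/>
        </xs:complexType>
      </xs:element>
    </xs:sequence>
    <xs:attribute name="tFirst" type="xs:double" use="required"/>
    <xs:attribute name="tLast" type="xs:double" use="required"/>
    <xs:attribute name="nPoints" type="xs:positiveInteger" use="required"/>
  </xs:complexType>

  <xs:complexType name="StreamType">
    <xs:simpleContent>
      <xs:extension base="xs:base64Binary">
        <xs:attribute name="species" type="bx:SId" use="required"/>
        <xs:attribute name="tstart" type="xs:double" use="required"/>
        <xs:attribute name="structure" type="xs:string"/>
        <xs:attribute name="kind" use="required">
          <xs:simpleType>
            <xs:restriction base="xs:string">
              <xs:enumeration value="integer"/>
              <xs:enumeration value="decimal"/>
            </xs:restriction>
          </xs:simpleType>
        </xs:attribute>
        <xs:attribute name="count" type="xs:nonNegativeInteger" use="required"/>
        <xs:attribute name="first" type="xs:double"/>
        <xs:attribute name="last" type="xs:double"/>
      </xs:extension>
    </xs:simpleContent>
  </xs:complexType>

  <xs:simpleType name="SId">
    <xs:restriction base="xs:string">
      <xs:pattern value="[A-Za-z_][A-Za-z0-9_]*"/>
    </xs:restriction>
  </xs:simpleType>

</xs:schema>
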