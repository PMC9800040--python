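"""XSD for the milestone-2 SBGN-ML dialect this package reads and writes.

Authored here to give :func:`ysbgn.sbgn_io.write_sbgnml` a machine-checkable
contract: namespace ``http://sbgn.org/libsbgn/0.2``, ``glyph`` elements before
``arc`` elements, ``bbox`` geometry as ``x/y/w/h`` attributes, nested glyphs
for complex members and auxiliary units, ``port`` children on processes and
``start``/``next``/``end`` points on arcs.  ``<extension>`` content is
deliberately unconstrained (any well-formed payload passes).
"""

from __future__ import annotations

from lxml import etree

SBGN_M2_NS = "http://sbgn.org/libsbgn/0.2"

SBGN_M2_XSD = f"""\
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="{SBGN_M2_NS}"
           xmlns:sbgn="{SBGN_M2_NS}"
           elementFormDefault="qualified">

  <xs:complexType name="extensionType">
    <xs:sequence>
      <xs:any minOccurs="0" maxOccurs="unbounded" processContents="skip"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="labelType">
    <xs:attribute name="text" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:complexType name="stateType">
    <xs:attribute name="value" type="xs:string"/>
    <xs:attribute name="variable" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="cloneType">
    <xs:sequence>
      <xs:element name="label" type="sbgn:labelType" minOccurs="0"/>
    </xs:sequence>
  </xs:complexType>

  <xs:complexType name="bboxType">
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
    <xs:attribute name="w" type="xs:double" use="required"/>
    <xs:attribute name="h" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="portType">
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="pointType">
    <xs:attribute name="x" type="xs:double" use="required"/>
    <xs:attribute name="y" type="xs:double" use="required"/>
  </xs:complexType>

  <xs:complexType name="glyphType">
    <xs:sequence>
      <xs:element name="extension" type="sbgn:extensionType" minOccurs="0"/>
      <xs:element name="label" type="sbgn:labelType" minOccurs="0"/>
      <xs:element name="state" type="sbgn:stateType" minOccurs="0"/>
      <xs:element name="clone" type="sbgn:cloneType" minOccurs="0"/>
      <xs:element name="bbox" type="sbgn:bboxType"/>
      <xs:element name="glyph" type="sbgn:glyphType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="port" type="sbgn:portType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="class" type="xs:string" use="required"/>
    <xs:attribute name="compartmentRef" type="xs:IDREF"/>
    <xs:attribute name="orientation" type="xs:string"/>
  </xs:complexType>

  <xs:complexType name="arcType">
    <xs:sequence>
      <xs:element name="extension" type="sbgn:extensionType" minOccurs="0"/>
      <xs:element name="start" type="sbgn:pointType"/>
      <xs:element name="next" type="sbgn:pointType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="end" type="sbgn:pointType"/>
    </xs:sequence>
    <xs:attribute name="id" type="xs:ID" use="required"/>
    <xs:attribute name="class" type="xs:string" use="required"/>
    <xs:attribute name="source" type="xs:IDREF" use="required"/>
    <xs:attribute name="target" type="xs:IDREF" use="required"/>
  </xs:complexType>

  <xs:complexType name="mapType">
    <xs:sequence>
      <xs:element name="extension" type="sbgn:extensionType" minOccurs="0"/>
      <xs:element name="glyph" type="sbgn:glyphType" minOccurs="0" maxOccurs="unbounded"/>
      <xs:element name="arc" type="sbgn:arcType" minOccurs="0" maxOccurs="unbounded"/>
    </xs:sequence>
    <xs:attribute name="language" type="xs:string" use="required"/>
  </xs:complexType>

  <xs:element name="sbgn">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="map" type="sbgn:mapType"/>
      </xs:sequence>
    </xs:complexType>
  </xs:element>

</xs:schema>
"""

_schema_cache: etree.XMLSchema | None = None


def milestone2_schema() -> etree.XMLSchema:
    global _schema_cache
    if _schema_cache is None:
        _schema_cache = etree.XMLSchema(etree.fromstring(SBGN_M2_XSD.encode()))
    return _schema_cache


def validates_against_m2(doc: etree._ElementTree | etree._Element) -> bool:
    return milestone2_schema().validate(doc)
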