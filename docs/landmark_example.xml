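<?xml version='1.0' encoding='utf-8'?>
<!-- Landmark file schema: one <landmarks> root per subject/segment, or a
     <subject id="..."> root wrapping several <landmarks segment="...">
     blocks. Coordinates are millimetres in the scan/export frame.
     Landmark names must be unique within a block. -->
<subject id="S01">
  <landmarks segment="first_metatarsal">
    <landmark name="TL" x="61.20" y="14.05" z="-8.91"/>
    <landmark name="TM" x="58.77" y="12.31" z="9.04"/>
    <landmark name="TB" x="-1.13" y="2.42" z="0.56"/>
  </landmarks>
  <landmarks segment="calcaneus">
    <landmark name="PT" x="22.18" y="-10.77" z="12.60"/>
    <landmark name="ST" x="18.94" y="3.16" z="-11.32"/>
    <landmark name="CA" x="-24.30" y="9.75" z="0.88"/>
  </landmarks>
</subject>
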