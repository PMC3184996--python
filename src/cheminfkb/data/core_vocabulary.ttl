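# Core vocabulary terms used by the knowledge-base layer: published
# CHEMINF/SIO identifiers with their labels, plus their subclass spine.
@prefix cheminf: <http://semanticscience.org/resource/> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .

cheminf:CHEMINF_000123 rdfs:label "chemical descriptor" .
cheminf:CHEMINF_000400 rdfs:label "chemical graph" ;
    rdfs:subClassOf cheminf:CHEMINF_000123 .
cheminf:CHEMINF_000113 rdfs:label "InChI descriptor" ;
    rdfs:subClassOf cheminf:CHEMINF_000123 .
cheminf:CHEMINF_000251 rdfs:label "LogP descriptor" ;
    rdfs:subClassOf cheminf:CHEMINF_000123 .
cheminf:CHEMINF_000186 rdfs:label "XLogP descriptor" ;
    rdfs:subClassOf cheminf:CHEMINF_000251 .
cheminf:CHEMINF_000014 rdfs:label "molecular entity information format specification" .
cheminf:CHEMINF_000144 rdfs:label "algorithm to calculate a chemical descriptor" .
cheminf:CHEMINF_000340 rdfs:label "software module" .
cheminf:CHEMINF_000103 rdfs:label "software module to calculate a chemical descriptor" ;
    rdfs:subClassOf cheminf:CHEMINF_000340 .
cheminf:CHEMINF_000031 rdfs:label "molecular entity quality" .
cheminf:CHEMINF_000101 rdfs:label "chemical substance quality" ;
    rdfs:subClassOf cheminf:CHEMINF_000031 .
cheminf:CHEMINF_000138 rdfs:label "software execution" .
cheminf:CHEMINF_000147 rdfs:label "parameterized software execution" ;
    rdfs:subClassOf cheminf:CHEMINF_000138 .
cheminf:CHEMINF_000200 rdfs:label "has attribute" .
cheminf:SIO_000300 rdfs:label "has value" .
cheminf:CHEMINF_000606 rdfs:label "is output of" .
cheminf:CHEMINF_000267 rdfs:label "OpenEye software" .
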