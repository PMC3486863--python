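# Default division-mapping configuration.
#
# domains: Venn-set label -> scientific name of the corresponding taxonomy
#   node (Viruses is a fourth top-level set, not a domain of life).
# merges: [source, target] pairs collapsed before division resolution, e.g.
#   annotations under Thaumarchaeota are binned with Crenarchaeota.
# supergroups: eukaryote node name -> supergroup label (Adl-style top groups);
#   division resolution for eukaryotes walks up the lineage to the first hit.
domains:
  Archaea: Archaea
  Bacteria: Bacteria
  Eukaryota: Eukaryota
  Viruses: Viruses
merges:
  - [Thaumarchaeota, Crenarchaeota]
supergroups:
  Amoebozoa: Amoebozoa
  Opisthokonta: Opisthokonta
  Rhizaria: Rhizaria
  Archaeplastida: Archaeplastida
  Chromalveolata: Chromalveolata
  Excavata: Excavata
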