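# Illustrative default pathway definitions: one pathway per substrate
# category, each a set of synthetic KO ids in the K##### format. The 80%
# presence threshold applies per genome. These defaults exercise the
# lineage-inference machinery and document the file format; supply a curated
# KO mapping for real analyses.
pathways:
  - name: hexose_degradation
    category: sugars
    kos: [K00100, K00101, K00102, K00103, K00104, K00105, K00106, K00107, K00108, K00109]
  - name: pentose_degradation
    category: sugars
    kos: [K00110, K00111, K00112, K00113, K00114, K00115, K00116, K00117, K00118, K00119]
  - name: amino_acid_catabolism
    category: amino_acids
    kos: [K00120, K00121, K00122, K00123, K00124, K00125, K00126, K00127, K00128, K00129]
  - name: scfa_oxidation
    category: scfa
    kos: [K00130, K00131, K00132, K00133, K00134, K00135, K00136, K00137, K00138, K00139]
  - name: lcfa_beta_oxidation
    category: lcfa_beta_oxidation
    kos: [K00140, K00141, K00142, K00143, K00144, K00145, K00146, K00147, K00148, K00149]
  - name: benzoate_degradation
    category: aromatics
    kos: [K00150, K00151, K00152, K00153, K00154, K00155, K00156, K00157, K00158, K00159]
  - name: alkane_degradation
    category: alkanes
    kos: [K00160, K00161, K00162, K00163, K00164, K00165, K00166, K00167, K00168, K00169]
  - name: wood_ljungdahl
    category: autotrophy
    kos: [K00170, K00171, K00172, K00173, K00174, K00175, K00176, K00177, K00178, K00179]
  - name: hydrogenotrophy
    category: hydrogen_oxidation
    kos: [K00180, K00181, K00182, K00183, K00184, K00185, K00186, K00187, K00188, K00189]
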