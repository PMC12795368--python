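# mispscreen

Screening for **modification-induced alternate peptide taxonomy** in
palaeoproteomics.

## The problem

In ancient-protein studies, the taxonomic claim attached to a detected
peptide rests on the lowest common ancestor (LCA) of all database proteins
containing that exact sequence. But two common post-translational
modifications make the observed letter sequence ambiguous:

* **Deamidation** converts Asn→Asp (N→D) and Gln→Glu (Q→E), adding
  +0.984 Da — exactly the mass difference between the residue pairs. A
  peptide reported as `TPEVDDEALEK` (Bovinae β-lactoglobulin) is therefore
  mass-indistinguishable from deamidated `TPEVDNEALEK` (*Ovis*): the sample
  could record cattle or sheep dairy.
* **N-terminal pyroglutamate** forms from Gln (−NH₃) or Glu (−H₂O); the
  resulting N-termini are isobaric, so a pyroGlu peptide's first residue
  could equally be Q or E.

Every alternative reading of this kind is a *modification-induced sequence
permutation* (MISP). A peptide with `s₁` deamidatable N/Q residues
(carrying `d` detected deamidation events), `s₂` D/E residues and an
optional N-terminal pyroGlu has

```
|MISPs| = ( Σ_{k=0..min(d,s₁)} C(s₁,k) ) · 2^{s₂} · (2 if pyroGlu else 1)
```

isobaric permutations (the unchanged sequence included) — up to thousands
for modification-rich peptides, far beyond what manual screening covers.

`mispscreen` enumerates all of them, resolves each to an LCA (via the
Unipept `pept2lca` service or an offline lookup table), classifies every
alternate LCA as *identical*, *more specific*, *less specific* or
*different* relative to the input peptide's LCA, and flags peptides whose
deamidation positions must be verified against the MS2 spectra before an
alternate LCA can be trusted.

It is a screening aid: it does not replace BLAST-based manual LCA
verification or protein-level interpretation.

## Worked example

Inputs are CSV/TSV tables with `Sequence`/`Modifications` (Mascot export)
or `pep_seq`/`pep_var_mod` (MaxQuant `evidence.txt`) columns. With the
packaged demonstration scenario (synthetic lineage table over real taxon
names):

```
python - <<'EOF'
from mispscreen.fixtures import write_worked_example
write_worked_example("demo")
EOF
mispscreen screen demo/worked_peptides.csv \
    --backend offline --offline-table-path demo/worked_lca_table.tsv \
    --out-dir demo --stem demo --stats
```

`demo/demo_results.csv` then contains one row per input peptide:

```
input_sequence,modifications,input_lca,total_misps,n_misps_with_lca,misps_with_lca,misp_lcas,all_lcas_identical,manual_check_required,category,notes
TPEVDDEALEK,,"Bovinae (taxon 27592, subfamily)",32,1,TPEVDNEALEK,"TPEVDNEALEK=Ovis (taxon 9935, genus)",False,False,different,
QEVGGEALGR,Gln->pyro-Glu (N-term Q),"Hippopotamus amphibius (taxon 9813, species)",8,1,EEVGGEALGR,"EEVGGEALGR=Sarcopterygii (taxon 8287, superclass)",False,False,less_specific,
GGGPGAGGLR,,,0,0,,,True,False,no_alternate,
```

Reading the rows: `TPEVDDEALEK` generates 32 isobaric permutations (2⁵
subsets of its five D/E sites), one of which matches a real protein with a
*different* lineage (*Ovis* vs Bovinae) — the classic dairy ambiguity.
`QEVGGEALGR` with pyroGlu has 8 permutations; its Q→E variant resolves to
Sarcopterygii, a *less specific* taxon than the implausibly precise
hippopotamus match, so the original species claim is insecure.
`GGGPGAGGLR` has no substitutable residues and no MISPs. A companion
permutations CSV lists every generated sequence, and a nested JSON holds
the full structure.

Against live Unipept (network required) simply drop the offline flags:

```
mispscreen screen peptides.csv --out-dir results --stats
```

`mispscreen simulate` generates seeded synthetic fixtures (peptide table,
offline LCA table derived from a toy taxonomy, and a manifest of expected
outcomes) used throughout the test suite.

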