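# ltpscan

A toolkit for genome-wide surveys of the plant non-specific lipid transfer
protein (nsLTP) gene family. nsLTPs are defined by an eight-cysteine motif
(ECM), `C-Xn-C-Xn-CC-Xn-CXC-Xn-C-Xn-C`, whose five inter-cysteine spacer
lengths distinguish family types. The package implements the full analysis
chain on plain-text inputs:

- **ECM detection and type classification** (`ecm_classifier`) — exhaustive
  motif scanning, spacing-template classification with a configurable
  registry, and a percent-identity similarity fallback for motifs that fit
  no template.
- **Per-protein characterization** (`physchem`) — length, average molecular
  weight (kDa), and theoretical pI (Bjellqvist pKa set, bisection).
- **Tandem-duplication calling** (`duplication`) — pairs of family genes
  separated by at most five other genes within 100 kb, clustered
  transitively; segmental anchors ingested from TSV; divergence dating via
  `t = Ks/(2r)` with `r = 2.6e-9` by default.
- **Ka/Ks estimation** (`kaks`) — Needleman–Wunsch protein alignment
  (BLOSUM62, affine gaps), codon back-translation, and Nei–Gojobori (1986)
  counting with Jukes–Cantor correction.
- **NJ phylogenetics** (`phylo`) — p-distance with pairwise deletion,
  Saitou–Nei neighbor joining with deterministic tie-breaking, and seeded
  column-bootstrap support.
- **Promoter cis-element scanning** (`promoter_elements`) — 1500-bp
  upstream windows, exact IUPAC matching on both strands, hits grouped into
  hormone (A) / stress (B) / growth (C) categories.
- **Synthetic data** (`synthetic_data`) — ground-truthed proteomes with
  planted motifs and decoys, gene maps with planted/decoy tandem clusters,
  and codon pairs with controlled synonymous/nonsynonymous divergence.
- **Pipeline** (`pipeline`) — orchestration of all stages from a flat
  key=value config file, with deterministic, seed-stamped TSV/Newick
  outputs.

## Command line

```sh
ltpscan classify  --proteome prot.fasta [--templates registry.tsv] --out types.tsv
ltpscan dups      --gff genes.gff3 --family ids.txt [--anchors anchors.tsv] --out clusters.tsv
ltpscan kaks      --cds cds.fasta --pairs pairs.tsv --out kaks.tsv
ltpscan tree      --alignment aln.fasta --bootstrap 1000 --seed 42 --out tree.nwk
ltpscan promoters --gff genes.gff3 --genome genome.fasta --motifs motifs.tsv --out hits.tsv
ltpscan simulate  {proteome|genemap|codonpair} --seed 1 --out DIR
ltpscan run       --config run.cfg
```

The template registry is a TSV with columns `type_name, s1..s5`; allowed
spacer sets use `a..b` range syntax (e.g. `12..17` or `6..10,13`). A potato
default registry for types I, II, IV, V, VII, VIII, XII and XIII is bundled.
Promoter motif tables are user-supplied TSVs (`name, pattern, category`);
only the element-name → category mapping ships with the package.

Config files for `ltpscan run` are flat `key = value` text (keys mirror
`pipeline.RunConfig`; `stages` is a comma list).

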