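# Ballesteros–Weinstein map fixtures

TSV files in the format `BWMap.from_tsv` reads
(`chain  res_seq  res_name  bw`).

- `demo_bundle_bw.tsv` — the map of the default synthetic 7×16 helix
  bundle (`switchscan.synth.default_demo_spec`); regenerable with
  `bundle_bw_map(spec).to_tsv(...)`.
- `t1r2_tmd_bw_synthetic_illustrative.tsv` — a **synthetic, illustrative**
  map for a TAS1R2 transmembrane domain (residues 562–818): helix spans
  and anchor positions are invented placeholders so that the commonly
  cited BW labels resolve for demonstration purposes.  They are *not*
  experimentally assigned sequence numbers; supply your own map for any
  real analysis.
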