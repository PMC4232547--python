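# Bundled toy fixtures

`toy_genotypes.tsv` / `toy_markers.tsv`: 20 samples x 7 markers on chr1,
constructed so each filter removes exactly one documented marker.

With `filter_markers(maf_min=0.01, call_rate_min=0.85, hwe_p_min=0.01)`:

| marker    | property                              | fate                      |
|-----------|---------------------------------------|---------------------------|
| m_mono    | monomorphic (MAF 0)                   | removed (MAF)             |
| m_rare    | one heterozygote (MAF 0.025)          | retained                  |
| m_lowcall | 16/20 calls (80% <= 85%, strict)      | removed (call rate)       |
| m_hwe     | 10 + 10 opposite homozygotes, no hets | removed (HWE p ~ 1e-5)    |
| m_ok1     | balanced 5/10/5                       | retained                  |
| m_dup     | exact copy of m_ok1 (later position)  | retained by filters       |
| m_ok2     | independent 8/8/4 (r2 to m_ok1 = 0)   | retained                  |

Then `ld_prune(r2_threshold=0.95)` removes `m_dup` (r2 = 1 with m_ok1; MAF
tie, so the later position goes).

Final retained set: `m_rare, m_ok1, m_ok2` (3 markers).
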