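marker_id	chrom	pos_bp	ref	alt
m_mono	chr1	100	A	T
m_rare	chr1	200	A	T
m_lowcall	chr1	300	A	T
m_hwe	chr1	400	A	T
m_ok1	chr1	500	A	T
m_dup	chr1	600	A	T
m_ok2	chr1	700	A	T
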