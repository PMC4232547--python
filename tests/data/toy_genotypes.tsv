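sample_id	m_mono	m_rare	m_lowcall	m_hwe	m_ok1	m_dup	m_ok2
s00	0	0	0	0	0	0	1
s01	0	0	NA	0	1	1	1
s02	0	0	2	0	0	0	0
s03	0	1	1	0	0	0	1
s04	0	0	NA	0	1	1	1
s05	0	0	1	0	2	2	0
s06	0	0	2	0	1	1	1
s07	0	0	1	0	1	1	2
s08	0	0	0	0	1	1	2
s09	0	0	1	0	1	1	2
s10	0	0	2	2	1	1	1
s11	0	0	1	2	0	0	0
s12	0	0	NA	2	1	1	2
s13	0	0	1	2	2	2	1
s14	0	0	2	2	2	2	0
s15	0	0	1	2	2	2	1
s16	0	0	0	2	1	1	0
s17	0	0	1	2	1	1	0
s18	0	0	2	2	2	2	0
s19	0	0	NA	2	0	0	0
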