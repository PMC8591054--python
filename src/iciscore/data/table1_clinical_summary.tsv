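category	level	count
os_status	status_0	489
os_status	status_1	16
histological_type	Classical.usual	361
histological_type	Follicular	99
histological_type	Tall.Cell	36
histological_type	Others	9
age	Age>60	113
age	Age<=60	392
gender	Female	367
gender	Male	138
stage	Stage_I	284
stage	Stage_II	52
stage	Stage_III	112
stage	Stage_IV	55
stage	Stage_un	2
m_stage	M0	286
m_stage	M1	8
m_stage	MX	210
m_stage	M_un	1
n_stage	N0	227
n_stage	N1	229
n_stage	NX	49
t_stage	T1	142
t_stage	T2	165
t_stage	T3	174
t_stage	T4	22
t_stage	TX	2
rt	YES	310
rt	NO	177
rt	UN	18
tmt	YES	5
tmt	NO	94
tmt	UN	406
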