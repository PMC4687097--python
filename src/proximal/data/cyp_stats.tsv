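cyp	abundance_avg	abundance_min	abundance_max	activity_avg	activity_min	activity_max
1A2	0.0895	0.0089	0.1232	0.0414	0.0000	0.0773
2A6	0.1245	0.0906	0.1888	0.1393	0.1189	0.1664
2B6	0.0177	0.0000	0.0906	0.0814	0.0450	0.0976
2C8	0.1003	0.0906	0.1232	0.1441	0.0976	0.1664
2C9	0.2226	0.1888	0.2498	0.1198	0.0000	0.1541
2C19	0.0114	0.0000	0.0154	0.0580	0.0000	0.1541
2D6	0.0069	0.0000	0.0154	0.0985	0.0450	0.1664
2E1	0.1898	0.0994	0.2498	0.1669	0.1389	0.2018
3A4	0.2374	0.1888	0.2498	0.1506	0.0000	0.2018
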