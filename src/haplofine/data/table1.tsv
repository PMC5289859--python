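chrom	pos	id	nonrisk_allele	risk_allele	annotation	lead	neglog10p	ppa	r2	dprime	or	ci_lo	ci_hi	excluded	genotyped
10	124203787	rs61871744	T	C	Intergenic	0	741.2	1.83e-42	0.952	0.995	2.787	2.693	2.885	1	0
10	124209684	rs11200630	T	C	Intergenic	0	774.5	3.56e-9	0.989	0.999	2.798	2.706	2.894	1	0
10	124210369	rs61871745	G	A	Intergenic	0	780.4	0.003	0.996	0.999	2.804	2.711	2.900	0	0
10	124211536	rs11200632	A	G	Intergenic	0	780.2	0.002	0.998	0.999	2.796	2.703	2.891	0	0
10	124211596	rs11200633	C	T	Intergenic	0	780.3	0.002	0.998	0.999	2.795	2.703	2.890	0	0
10	124212913	rs61871746	T	C	Intergenic	0	781.3	0.024	0.998	1.000	2.794	2.702	2.889	0	0
10	124213046	rs61871747	C	T	Intergenic	0	781.5	0.033	0.998	1.000	2.793	2.701	2.888	0	0
10	124214448	rs10490924	G	T	ARMS2: p.A69S	0	781.8	0.076	0.998	1.000	2.786	2.694	2.881	0	1
10	124214600	10:124214600	G	GGT	ARMS2: intronic	0	781.9	0.091	0.998	1.000	2.787	2.695	2.881	0	0
10	124214976	rs36212731	G	T	ARMS2: intronic	0	781.9	0.094	0.999	1.000	2.787	2.695	2.881	0	0
10	124215198	rs36212732	A	G	ARMS2: intronic	0	781.9	0.085	0.999	1.000	2.786	2.695	2.881	0	1
10	124215211	rs36212733	T	C	ARMS2: intronic	0	782.0	0.110	0.999	1.000	2.787	2.695	2.881	0	0
10	124215315	rs3750848	T	G	ARMS2: intronic	0	782.1	0.139	0.999	1.000	2.787	2.695	2.882	0	0
10	124215421	rs3750847	C	T	ARMS2: intronic	0	782.2	0.168	0.999	1.000	2.787	2.695	2.882	0	1
10	124215565	rs3750846	T	C	ARMS2: intronic	1	782.2	0.173	1.000	1.000	2.787	2.695	2.882	0	0
10	124216820	esv2663177	443bp	54bp	ARMS2: UTR del442ins54	0	770.0	1.02e-13	0.981	0.991	2.762	2.671	2.856	1	0
10	124219275	rs3793917	C	G	Intergenic	0	768.0	1.10e-15	0.979	0.990	2.756	2.665	2.849	1	1
10	124220061	rs3763764	A	G	Intergenic	0	759.6	4.05e-24	0.965	0.989	2.746	2.656	2.839	1	0
10	124220544	rs11200638	G	A	HTRA1: Promoter	0	755.9	9.29e-28	0.963	0.988	2.737	2.647	2.830	1	1
10	124221270	rs1049331	C	T	HTRA1: p.A34A	0	755.6	5.06e-28	0.961	0.987	2.744	2.654	2.838	1	0
10	124221276	rs2293870	G	T	HTRA1: p.G36G	0	755.5	3.44e-28	0.961	0.987	2.744	2.654	2.838	1	0
10	124226630	rs2284665	G	T	HTRA1: intronic	0	742.4	3.10e-41	0.933	0.974	2.724	2.634	2.817	1	0
10	124230024	rs58077526	A	C	HTRA1: intronic	0	716.7	5.71e-67	0.896	0.958	2.672	2.584	2.763	1	0
10	124231464	rs932275	G	A	HTRA1: intronic	0	716.7	5.23e-67	0.899	0.962	2.678	2.590	2.770	1	0
10	124234037	rs2142308	G	C	HTRA1: intronic	0	711.1	1.45e-72	0.888	0.956	2.666	2.578	2.756	1	0
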