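marker	k	Ho	He	PIC	MP	PE1P	PE2P	PESI	hw_significant
BM1824	4	0.711	0.745	0.694	0.114	0.319	0.668	0.592	0
BM2113	8	0.816	0.824	0.797	0.062	0.469	0.821	0.646	0
ETH03	8	0.588	0.621	0.582	0.181	0.224	0.597	0.513	0
ETH010	6	0.746	0.710	0.658	0.160	0.295	0.649	0.570	0
ETH225	6	0.684	0.639	0.604	0.161	0.241	0.623	0.527	0
INRA023	7	0.737	0.769	0.729	0.088	0.373	0.736	0.610	0
SPS115	6	0.596	0.581	0.522	0.235	0.182	0.503	0.481	0
TGLA53	11	0.754	0.820	0.791	0.063	0.462	0.815	0.643	0
TGLA122	11	0.746	0.768	0.734	0.084	0.387	0.758	0.611	0
TGLA126	5	0.658	0.608	0.556	0.201	0.203	0.545	0.502	0
TGLA227	11	0.860	0.865	0.845	0.039	0.559	0.882	0.672	0
BM1818	7	0.728	0.783	0.750	0.080	0.401	0.770	0.620	0
CSSM66	12	0.732	0.777	0.755	0.078	0.422	0.808	0.619	0
CSRM60	7	0.652	0.632	0.602	0.163	0.240	0.633	0.523	0
ILSTS006	7	0.719	0.806	0.774	0.070	0.432	0.789	0.634	0
HAUT27	7	0.693	0.745	0.702	0.111	0.342	0.706	0.594	0
MM12	11	0.842	0.804	0.777	0.086	0.445	0.810	0.634	0
HEL09	7	0.754	0.798	0.764	0.075	0.417	0.776	0.629	0
INRA032	8	0.693	0.747	0.710	0.099	0.351	0.725	0.597	0
ETH152	6	0.788	0.746	0.701	0.124	0.336	0.696	0.594	0
HAUT024	8	0.772	0.737	0.691	0.123	0.327	0.687	0.589	0
INRA037	9	0.268	0.663	0.601	0.231	0.250	0.588	0.536	1
INRA005	4	0.604	0.642	0.564	0.198	0.206	0.500	0.518	0
ETH185	8	0.536	0.596	0.554	0.222	0.202	0.563	0.496	0
HEL05	8	0.561	0.567	0.535	0.217	0.185	0.555	0.477	0
INRA063	4	0.563	0.576	0.506	0.243	0.172	0.469	0.474	0
HEL01	5	0.554	0.558	0.505	0.254	0.165	0.486	0.466	0
HEL13	5	0.482	0.469	0.421	0.352	0.113	0.400	0.401	0
INRA035	3	0.298	0.427	0.384	0.397	0.091	0.357	0.370	0
ILST005	2	0.351	0.372	0.302	0.463	0.069	0.237	0.319	0
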