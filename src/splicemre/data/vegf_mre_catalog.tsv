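gene_id	mirna_id	start	end	repressive_ratio	validation	supported_cancer	supported_normal
VEGF	hsa-miR-125a	1742	1782	15	true	Thyroid
VEGF	hsa-miR-140	1742	1782	48	true	Thyroid
VEGF	hsa-miR-17-5p	1899	1921	35	true
VEGF	hsa-miR-20a	1899	1921	39	true
VEGF	hsa-miR-20b	1899	1921	41	true
VEGF	hsa-miR-106a	1899	1921	21	true
VEGF	hsa-miR-106b	1899	1921	35	true
VEGF	hsa-miR-302d	1899	1921	30	true
VEGF	hsa-miR-372	1899	1921	30	true
VEGF	hsa-miR-520g	1899	1921	19	true
VEGF	hsa-miR-520h	1899	1921	28	true
VEGF	hsa-miR-302d	1935	1955	40	true	Ovary
VEGF	hsa-miR-15a	1992	2020	50	true
VEGF	hsa-miR-16	1992	2020	51	true
VEGF	hsa-miR-195	1992	2020	45	true
VEGF	hsa-miR-150	2221	2243	30	true
VEGF	hsa-miR-205	2258	2282	13	true
VEGF	hsa-miR-15b	2508	2554	25	true	Salivary gland	Liver
VEGF	hsa-miR-107	2508	2554	42	true	Salivary gland	Liver
VEGF	hsa-miR-147	2508	2554	39	true	Salivary gland	Liver
VEGF	hsa-miR-330	2508	2554	25	true	Salivary gland	Liver
VEGF	hsa-miR-34a	2567	2601	15	true
VEGF	hsa-miR-34b	2567	2601	8	true
VEGF	hsa-miR-373	2567	2601	22	true
VEGF	hsa-miR-378	2567	2601	17	true
VEGF	hsa-miR-504	3009	3029	30	true	Brain
VEGF	hsa-miR-383	3134	3160	25	true
VEGF	hsa-miR-134	3151	3172	45	true		Pancreatic islet
VEGF	hsa-miR-361	3342	3362	45	true
VEGF	hsa-miR-29b	3466	3486	18	true
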