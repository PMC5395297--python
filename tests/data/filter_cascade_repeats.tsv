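feature	chrom	start	end	fdr	lfc	mutant_unique	wt_unique	expected_call	expected_confirm
chr1:1000-1300	chr1	1000	1300	0.001	1.5	25	5	up	confirmed
chr1:2000-2300	chr1	2000	2300	0.002	0.8	20	4	gene_overlap	
chr1:3000-3300	chr1	3000	3300	0.005	0.5	9	1	up	not_assessable
chr1:4000-4300	chr1	4000	4300	0.004	2.0	30	25	up	not_confirmed
chr1:5000-5300	chr1	5000	5300	0.003	1.0	40	6	up	confirmed
chr1:6000-6300	chr1	6000	6300	0.005	0.0	15	3	not_called	
chr1:7000-7300	chr1	7000	7300	0.02	2.0	50	5	not_called	
chr1:8000-8300	chr1	8000	8300	0.009	0.01	22	4	up	confirmed
chr1:9000-9300	chr1	9000	9300	0.001	1.0	18	4	gene_overlap	
chr1:10000-10300	chr1	10000	10300	0.001	1.0	11	1	up	confirmed
chr1:11000-11300	chr1	11000	11300	0.001	1.0	10	1	up	not_assessable
chr1:12000-12300	chr1	12000	12300	0.008	0.3	35	30	up	not_confirmed
chr1:13000-13300	chr1	13000	13300	0.5	1.0	20	2	not_called	
chr1:14000-14300	chr1	14000	14300	0.011	0.5	20	2	not_called	
chr1:15000-15300	chr1	15000	15300	0.009	-0.5	20	2	not_called	
chr1:16000-16300	chr1	16000	16300	0.002	3.0	100	10	gene_overlap	
chr1:17000-17300	chr1	17000	17300	0.0005	0.2	60	5	up	confirmed
chr1:18000-18300	chr1	18000	18300	0.9	-2.0	5	50	not_called	
chr1:19000-19300	chr1	19000	19300	0.006	1.2	12	11	up	not_confirmed
chr1:20000-20300	chr1	20000	20300	0.003	0.7	200	20	up	confirmed
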