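# Per-element constants used by the constitutional-descriptor key.
# mass: standard atomic weight (u).
# vdw_volume: van der Waals volume relative to carbon, (r/r_C)^3 from Bondi radii (r_C = 1.70 A).
# sanderson_en: Sanderson electronegativity relative to carbon (2.746).
# polarizability: static atomic polarizability relative to carbon (1.76 1e-24 cm^3).
element	mass	vdw_volume	sanderson_en	polarizability
H	1.008	0.353	0.944	0.379
Li	6.940	1.227	0.244	13.807
Be	9.012	0.729	0.659	3.182
B	10.811	1.441	0.828	1.722
C	12.011	1.000	1.000	1.000
N	14.007	0.758	1.163	0.625
O	15.999	0.715	1.331	0.456
F	18.998	0.647	1.457	0.316
Na	22.990	2.381	0.204	13.699
Mg	24.305	1.054	0.480	6.023
Si	28.086	1.885	0.779	3.057
P	30.974	1.187	0.916	2.063
S	32.060	1.187	1.077	1.648
Cl	35.453	1.091	1.265	1.239
K	39.098	4.233	0.162	24.659
Ca	40.078	2.509	0.345	12.955
Zn	65.380	0.547	0.810	3.267
As	74.922	1.289	1.025	2.449
Se	78.971	1.396	1.098	2.142
Br	79.904	1.289	1.172	1.733
Sn	118.710	2.080	0.837	4.375
I	126.904	1.580	1.012	3.040
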