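name	mz	composition	reduced_end	feature	esnog_cutoff
HexNAc-red-167	167.0914		true	other	0.01
Hex-red	183.0863	Hex1	true	other	0.01
HexNAc	204.0867	HexNAc1	false	other	0.01
HexNAc+H2O	222.0972		false	other	0.01
HexNAc-red	224.1118	HexNAc1	true	n_glycan	0.03
Hex-phospho	243.0264		false	other	0.01
Neu5Ac-H2O	274.0921		false	neu5ac	0.01
HexNAc-SO4	284.0435	HexNAc1SO41	false	sulfo_hexnac	0.01
Neu5Gc-H2O	290.087		false	neu5gc	0.01
Neu5Ac	292.1027	Neu5Ac1	false	neu5ac	0.01
Neu5Gc	308.0976	Neu5Gc1	false	neu5gc	0.01
Neu5Ac-red	312.1289	Neu5Ac1	true	other	0.01
AcNeu5Ac-H2O	316.1027		false	other	0.01
Neu5Gc-red	328.1238	Neu5Gc1	true	other	0.01
AcNeu5Gc-H2O	332.0976		false	other	0.01
AcNeu5Ac	334.1133	Neu5Ac1Ac1	false	oac_neu5ac	0.01
AcNeu5Gc	350.1082	Neu5Gc1Ac1	false	oac_neu5gc	0.01
LacNAc	366.1395	Hex1HexNAc1	false	other	0.01
HexNAc-Fuc-red	370.1697	HexNAc1Fuc1	true	other	0.01
HexNAc2	407.1661	HexNAc2	false	other	0.01
LacNAc-SO4	446.09627	Hex1HexNAc1SO41	false	other	0.01
Neu5Ac-HexNAc	495.1821	HexNAc1Neu5Ac1	false	sia_hexnac_ac	0.01
Neu5Gc-HexNAc	511.177	HexNAc1Neu5Gc1	false	sia_hexnac_gc	0.01
Fuc-LacNAc	512.1974	Hex1HexNAc1Fuc1	false	fucose_antenna	0.01
Hex2HexNAc	528.1923	Hex2HexNAc1	false	alpha_gal	0.01
HNK1	542.1716	Hex1HexNAc1HexA1	false	hnk1	0.01
Fuc-LacdiNAc	553.224	HexNAc2Fuc1	false	lacdinac_fuc	0.01
HexHexNAc2	569.21887	Hex1HexNAc2	false	other	0.01
HNK1-SO4	622.1284	Hex1HexNAc1HexA1SO41	false	hnk1_sulfo	0.01
HexHexNAc2-SO4	649.17567	Hex1HexNAc2SO41	false	other	0.01
Neu5Ac-LacNAc	657.2349	Hex1HexNAc1Neu5Ac1	false	other	0.01
LewisY	658.2553	Hex1HexNAc1Fuc2	false	lewis_y	0.01
Neu5Gc-LacNAc	673.2298	Hex1HexNAc1Neu5Gc1	false	other	0.01
Neu5Ac-LacdiNAc	698.2615	HexNAc2Neu5Ac1	false	other	0.01
AcNeu5Ac-LacNAc	699.2455	Hex1HexNAc1Neu5Ac1Ac1	false	other	0.01
Neu5Gc-LacdiNAc	714.2564	HexNAc2Neu5Gc1	false	other	0.01
AcNeu5Gc-LacNAc	715.2404	Hex1HexNAc1Neu5Gc1Ac1	false	other	0.01
Fuc-HexHexNAc2	715.27677	Hex1HexNAc2Fuc1	false	other	0.01
Hex2HexNAc2	731.27167	Hex2HexNAc2	false	other	0.01
Bisect-red	792.3234	Hex1HexNAc3	true	bisecting	0.01
SialylLewisX	803.2928	Hex1HexNAc1Fuc1Neu5Ac1	false	other	0.01
Neu5Gc-Fuc-LacNAc	819.2877	Hex1HexNAc1Fuc1Neu5Gc1	false	other	0.01
Sda	860.31427	Hex1HexNAc2Neu5Ac1	false	sda	0.01
Sda-Gc	876.30917	Hex1HexNAc2Neu5Gc1	false	other	0.01
Fuc-Hex2HexNAc2	877.32957	Hex2HexNAc2Fuc1	false	other	0.01
DisialylLewisC	948.3303	Hex1HexNAc1Neu5Ac2	false	disialyl_lewis_c_ac	0.01
DisialylLewisC-Gc	980.3201	Hex1HexNAc1Neu5Gc2	false	disialyl_lewis_c_gc	0.01
Fuc2-Hex2HexNAc2	1023.38747	Hex2HexNAc2Fuc2	false	other	0.01
Fuc3-Hex2HexNAc2	1169.44537	Hex2HexNAc2Fuc3	false	other	0.01
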