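# Synthetic re-tabulation of human hemoglobin molar extinction coefficients.
# Smooth anchor values approximating the published oxyhemoglobin (Zijlstra-family)
# and deoxyhemoglobin (Prahl-family) compilations; reconstructed for this package,
# NOT copied from any database, and accurate only to roughly +/-15 percent.
# The spectral structure (Q-band twin peaks of HbO2 at ~542/576 nm, single Hb peak
# at ~555 nm, deoxy bump near 758 nm, isosbestic crossing near ~797 nm) is preserved.
#
# Columns:
#   wavelength_nm        vacuum wavelength [nm]
#   eps_hbo2_cm1_M       decadic molar extinction of oxyhemoglobin  [cm^-1 / (mol Hb / L)]
#   eps_hb_cm1_M         decadic molar extinction of deoxyhemoglobin [cm^-1 / (mol Hb / L)]
#
# Conversion to whole-blood absorption (done in code, natural-log convention):
#   mu_a [mm^-1] = ln(10) * eps [cm^-1/M] * C_Hb [M] / 10
# with C_Hb = hematocrit * MCHC / M_Hb = 0.43 * 345 g/L / 64500 g/mol = 2.3003e-3 M.
wavelength_nm	eps_hbo2_cm1_M	eps_hb_cm1_M
450	62816	65000
460	44480	55000
470	33209	43000
480	26629	33000
490	23100	25500
500	20932	20862
510	20350	23500
520	24600	28500
529	37000	37000
535	46000	42500
540	53236	46592
542	55000	48000
545	50500	50500
548	48000	51500
555	38500	53412
560	32613	51600
565	34500	49000
570	44500	44500
576	56000	38500
580	50000	37020
584	33000	33000
590	17000	26600
595	7800	20500
600	3200	14677
610	1506	11000
620	942	9400
630	610	6500
640	442	4900
650	368	3750
660	320	3227
670	300	2795
680	288	2407
690	284	2051
700	290	1794
710	310	1540
720	340	1312
730	390	1102
740	446	1250
750	518	1405
760	586	1549
770	650	1300
780	710	1075
790	774	880
800	816	762
810	864	740
820	916	710
840	1022	693
850	1058	692
870	1115	705
880	1154	724
900	1198	762
910	1220	780
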