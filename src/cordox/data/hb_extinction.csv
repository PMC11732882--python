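wavelength_nm,eps_hbo2,eps_hbr
650,368.0,3750.0
660,319.6,3226.6
670,294.0,2795.1
680,277.6,2407.9
690,276.0,2052.0
700,290.0,1794.3
710,314.0,1540.5
720,348.0,1325.9
730,390.0,1102.2
740,446.0,1200.0
750,518.0,1405.2
760,586.0,1548.5
770,650.0,1311.9
780,710.0,1075.4
790,756.0,903.0
800,816.0,761.7
810,864.0,717.1
820,916.0,693.8
830,974.0,693.0
840,1022.0,692.4
850,1058.0,691.3
860,1092.0,696.0
870,1128.0,707.0
880,1154.0,726.0
890,1186.0,751.0
900,1198.0,762.0
910,1232.0,775.0
920,1264.0,784.0
930,1278.0,798.0
940,1290.0,810.0
950,1250.0,820.0
960,1230.0,832.0
970,1210.0,844.0
980,1190.0,856.0
990,1170.0,868.0
1000,1150.0,880.0
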