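# Per-site mean peak force (N) and CV (%) from triplicate indentation
# mappings of 10 control femoral condyles; transcription of the source
# study's per-site table. Missing cells are empty.
site_id,specimen,mean_N,cv_pct
L1,S01,0.08,2.9
L1,S02,0.08,3.0
L1,S03,0.1,4.1
L1,S04,0.13,1.8
L1,S05,0.09,12.1
L1,S06,0.1,2.7
L1,S07,0.1,4.9
L1,S08,0.09,3.3
L1,S09,0.07,1.5
L1,S10,0.11,0.2
L2,S01,0.11,1.3
L2,S02,0.09,2.5
L2,S03,0.1,2.3
L2,S04,0.14,6.1
L2,S05,0.12,8.2
L2,S06,0.11,4.5
L2,S07,0.13,4.9
L2,S08,0.11,6.1
L2,S09,0.07,13.7
L2,S10,0.11,5.7
L3,S01,0.07,4.9
L3,S02,0.08,3.6
L3,S03,0.08,5.0
L3,S04,0.12,2.5
L3,S05,0.11,4.8
L3,S06,0.12,1.5
L3,S07,0.09,3.8
L3,S08,0.08,4.9
L3,S09,0.07,8.5
L3,S10,0.08,8.0
L4,S01,0.1,7.2
L4,S02,0.07,2.8
L4,S03,0.1,1.3
L4,S04,0.11,1.6
L4,S05,0.08,3.6
L4,S06,0.11,4.7
L4,S07,0.13,2.2
L4,S08,0.09,3.0
L4,S09,0.06,4.8
L4,S10,0.09,5.5
L5,S01,0.16,0.7
L5,S02,0.15,5.0
L5,S03,0.21,9.0
L5,S04,0.14,7.7
L5,S05,0.12,7.8
L5,S06,0.04,10.0
L5,S07,0.17,2.4
L5,S08,0.17,4.2
L5,S09,0.11,6.0
L5,S10,0.19,6.3
L6,S01,0.06,9.3
L6,S02,0.07,7.4
L6,S03,0.08,13.4
L6,S04,0.12,4.1
L6,S05,0.09,5.7
L6,S06,0.08,2.9
L6,S07,0.06,9.0
L6,S08,0.06,6.9
L6,S09,0.08,6.0
L6,S10,0.07,5.8
L7,S01,0.06,4.7
L7,S02,0.07,6.2
L7,S03,0.08,6.9
L7,S04,0.1,3.1
L7,S05,0.07,12.3
L7,S06,0.07,3.8
L7,S07,0.09,8.0
L7,S08,0.08,4.9
L7,S09,0.07,3.8
L7,S10,0.07,7.5
L8,S01,0.16,2.2
L8,S02,0.09,15.9
L8,S03,0.19,3.2
L8,S04,0.14,4.9
L8,S05,0.11,7.9
L8,S06,,
L8,S07,0.2,5.8
L8,S08,0.17,3.1
L8,S09,0.12,3.5
L8,S10,0.12,6.5
L9,S01,0.05,10.3
L9,S02,0.07,5.4
L9,S03,0.08,2.4
L9,S04,0.09,1.5
L9,S05,0.03,20.2
L9,S06,0.07,0.3
L9,S07,0.05,6.4
L9,S08,0.07,2.9
L9,S09,0.09,0.9
L9,S10,0.08,2.5
L10,S01,0.04,4.2
L10,S02,0.07,6.8
L10,S03,0.07,3.1
L10,S04,0.08,4.5
L10,S05,,
L10,S06,0.08,3.3
L10,S07,0.07,3.9
L10,S08,0.07,5.5
L10,S09,0.07,1.1
L10,S10,0.08,3.2
L11,S01,0.1,5.7
L11,S02,0.08,6.1
L11,S03,0.15,2.4
L11,S04,0.11,9.1
L11,S05,0.13,5.1
L11,S06,0.14,6.8
L11,S07,0.16,5.9
L11,S08,0.14,3.7
L11,S09,0.04,9.0
L11,S10,0.11,1.3
L12,S01,0.05,0.9
L12,S02,0.08,4.6
L12,S03,0.07,9.4
L12,S04,0.07,3.6
L12,S05,,
L12,S06,0.09,3.1
L12,S07,0.06,6.2
L12,S08,0.06,8.8
L12,S09,0.11,3.6
L12,S10,0.1,3.3
L13,S01,0.05,3.0
L13,S02,0.07,3.6
L13,S03,0.07,6.4
L13,S04,0.07,5.8
L13,S05,,
L13,S06,0.1,2.3
L13,S07,0.07,2.9
L13,S08,0.08,4.9
L13,S09,0.09,0.9
L13,S10,0.09,6.0
L14,S01,0.08,5.0
L14,S02,0.08,5.7
L14,S03,0.13,4.9
L14,S04,0.1,4.9
L14,S05,0.04,19.0
L14,S06,0.14,1.1
L14,S07,0.14,3.7
L14,S08,0.16,1.7
L14,S09,0.09,12.0
L14,S10,0.12,1.4
M1,S01,0.29,3.7
M1,S02,0.18,6.9
M1,S03,0.23,4.1
M1,S04,0.23,1.9
M1,S05,0.21,5.5
M1,S06,0.26,1.4
M1,S07,0.22,6.7
M1,S08,0.2,2.2
M1,S09,0.2,1.7
M1,S10,0.22,1.9
M2,S01,,
M2,S02,0.25,4.6
M2,S03,0.25,3.2
M2,S04,0.26,1.0
M2,S05,0.28,2.3
M2,S06,0.29,2.1
M2,S07,0.27,1.5
M2,S08,0.24,6.3
M2,S09,0.2,5.4
M2,S10,0.29,0.9
M3,S01,0.23,3.1
M3,S02,0.17,3.8
M3,S03,0.24,0.7
M3,S04,0.24,1.4
M3,S05,0.24,2.8
M3,S06,0.24,1.8
M3,S07,0.23,3.2
M3,S08,0.19,2.7
M3,S09,0.22,6.7
M3,S10,0.25,3.4
M4,S01,0.36,5.0
M4,S02,0.3,6.5
M4,S03,0.28,0.6
M4,S04,0.3,2.6
M4,S05,0.29,3.1
M4,S06,0.31,2.7
M4,S07,0.25,5.8
M4,S08,0.26,3.1
M4,S09,0.19,4.5
M4,S10,0.3,2.7
M5,S01,,
M5,S02,0.38,10.0
M5,S03,0.3,3.9
M5,S04,0.3,1.9
M5,S05,0.36,1.1
M5,S06,0.26,0.7
M5,S07,0.3,2.4
M5,S08,0.25,5.5
M5,S09,0.18,4.3
M5,S10,0.15,5.1
M6,S01,0.19,1.7
M6,S02,0.17,6.3
M6,S03,0.25,3.4
M6,S04,0.23,3.8
M6,S05,0.19,5.6
M6,S06,0.26,2.3
M6,S07,0.21,0.7
M6,S08,0.11,10.9
M6,S09,0.16,3.9
M6,S10,0.2,15.1
M7,S01,0.3,3.3
M7,S02,0.3,4.2
M7,S03,0.34,5.9
M7,S04,0.3,1.9
M7,S05,0.37,7.0
M7,S06,0.31,1.7
M7,S07,0.26,2.2
M7,S08,0.28,1.1
M7,S09,0.16,1.4
M7,S10,0.3,6.9
M8,S01,0.37,3.3
M8,S02,0.36,6.2
M8,S03,0.33,2.0
M8,S04,0.28,5.1
M8,S05,0.35,5.6
M8,S06,0.23,2.0
M8,S07,0.23,6.0
M8,S08,0.17,3.6
M8,S09,0.13,1.7
M8,S10,0.14,4.2
M9,S01,0.2,3.8
M9,S02,0.16,2.5
M9,S03,0.27,5.6
M9,S04,0.21,2.8
M9,S05,0.18,19.6
M9,S06,0.25,1.2
M9,S07,0.2,4.2
M9,S08,0.16,0.9
M9,S09,0.15,3.4
M9,S10,0.24,18.6
M10,S01,0.26,2.8
M10,S02,0.3,2.0
M10,S03,0.33,7.1
M10,S04,0.28,1.2
M10,S05,0.39,2.2
M10,S06,0.25,2.4
M10,S07,0.19,2.5
M10,S08,0.25,2.0
M10,S09,0.16,2.4
M10,S10,0.24,2.7
M11,S01,0.28,2.0
M11,S02,0.3,2.8
M11,S03,0.3,6.0
M11,S04,0.21,1.6
M11,S05,0.31,3.8
M11,S06,0.22,2.0
M11,S07,0.16,1.1
M11,S08,0.14,0.7
M11,S09,0.13,7.8
M11,S10,0.11,7.1
M12,S01,0.16,1.6
M12,S02,0.19,5.9
M12,S03,0.25,1.6
M12,S04,0.18,0.6
M12,S05,0.17,2.3
M12,S06,0.18,6.4
M12,S07,0.15,6.9
M12,S08,0.18,5.7
M12,S09,0.09,7.7
M12,S10,,
M13,S01,0.22,4.3
M13,S02,0.26,4.6
M13,S03,0.29,3.0
M13,S04,0.2,2.3
M13,S05,0.32,4.0
M13,S06,0.2,2.6
M13,S07,0.15,1.2
M13,S08,0.21,3.6
M13,S09,0.14,0.1
M13,S10,0.2,2.9
M14,S01,0.19,1.6
M14,S02,0.27,1.2
M14,S03,0.25,4.2
M14,S04,0.17,2.6
M14,S05,0.27,1.2
M14,S06,0.2,0.8
M14,S07,0.14,2.9
M14,S08,0.13,4.1
M14,S09,0.12,3.2
M14,S10,0.12,1.8
M15,S01,0.16,3.7
M15,S02,0.16,0.5
M15,S03,0.18,1.6
M15,S04,0.14,1.6
M15,S05,0.18,0.7
M15,S06,0.13,1.9
M15,S07,0.13,1.7
M15,S08,0.14,1.1
M15,S09,0.14,1.6
M15,S10,0.21,9.2
M16,S01,0.14,1.3
M16,S02,0.19,1.3
M16,S03,0.2,0.9
M16,S04,0.14,2.1
M16,S05,0.22,1.4
M16,S06,0.16,2.7
M16,S07,0.12,0.8
M16,S08,0.15,1.2
M16,S09,0.13,1.4
M16,S10,0.16,1.7
M17,S01,0.14,2.2
M17,S02,0.21,1.1
M17,S03,0.17,3.4
M17,S04,0.15,2.6
M17,S05,0.19,3.1
M17,S06,0.15,5.5
M17,S07,0.13,2.1
M17,S08,0.12,3.0
M17,S09,0.13,1.4
M17,S10,0.13,2.2
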