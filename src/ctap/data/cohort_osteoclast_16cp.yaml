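# The 16-comparison-pair osteoclast-differentiation cohort design: 8 pairs in
# which the test population drives differentiation up (OCU) and 8 in which it
# drives differentiation down (OCD), drawn from 11 independent expression
# studies.  Sample identifiers are synthetic placeholders (the public series'
# per-sample accessions are not bundled); population labels describe the
# biological grouping each placeholder stands for.
cps:
  - cp_id: 1
    study_id: GSE111237
    platform_id: GPL6885
    context: OCU
    control: {label: "osteoclast progenitors", samples: [CP01.C1, CP01.C2, CP01.C3]}
    test: {label: "mature-osteoclast progenitors", samples: [CP01.T1, CP01.T2, CP01.T3]}
  - cp_id: 2
    study_id: GSE142866
    platform_id: GPL17021
    context: OCU
    control: {label: "No RANKL", samples: [CP02.C1, CP02.C2, CP02.C3]}
    test: {label: "RANKL", samples: [CP02.T1, CP02.T2, CP02.T3]}
  - cp_id: 3
    study_id: GSE142866
    platform_id: GPL17021
    context: OCD
    control: {label: "RANKL", samples: [CP03.C1, CP03.C2, CP03.C3]}
    test: {label: "RANKL with LEA", samples: [CP03.T1, CP03.T2, CP03.T3]}
  - cp_id: 4
    study_id: GSE149887
    platform_id: GPL21103
    context: OCU
    control: {label: "Mo (macrophages)", samples: [CP04.C1, CP04.C2, CP04.C3]}
    test: {label: "Oc (osteoclasts)", samples: [CP04.T1, CP04.T2, CP04.T3]}
  - cp_id: 5
    study_id: GSE17563
    platform_id: GPL339
    context: OCU
    control: {label: "bone marrow treated with hRANKL 0 hr", samples: [CP05.C1, CP05.C2, CP05.C3]}
    test: {label: "bone marrow treated with hRANKL 24h", samples: [CP05.T1, CP05.T2, CP05.T3]}
  - cp_id: 6
    study_id: GSE17563
    platform_id: GPL339
    context: OCU
    control: {label: "bone marrow treated with hRANKL 0 hr", samples: [CP06.C1, CP06.C2, CP06.C3]}
    test: {label: "bone marrow treated with hRANKL 72h", samples: [CP06.T1, CP06.T2, CP06.T3]}
  - cp_id: 7
    study_id: GSE20850
    platform_id: GPL1261
    context: OCU
    control: {label: "Macrophages", samples: [CP07.C1, CP07.C2, CP07.C3]}
    test: {label: "Osteoclasts", samples: [CP07.T1, CP07.T2, CP07.T3]}
  - cp_id: 8
    study_id: GSE30160
    platform_id: GPL1261
    context: OCD
    control: {label: "WT", samples: [CP08.C1, CP08.C2, CP08.C3]}
    test: {label: "RANK IVVY Knockin", samples: [CP08.T1, CP08.T2, CP08.T3]}
  - cp_id: 9
    study_id: GSE37219
    platform_id: GPL8321
    context: OCD
    control: {label: "WT", samples: [CP09.C1, CP09.C2, CP09.C3]}
    test: {label: "NFATc1-deficient OC", samples: [CP09.T1, CP09.T2, CP09.T3]}
  - cp_id: 10
    study_id: GSE57468
    platform_id: GPL6885
    context: OCD
    control: {label: "BMM RANKL 1day", samples: [CP10.C1, CP10.C2, CP10.C3]}
    test: {label: "BMM RANKL 0day", samples: [CP10.T1, CP10.T2, CP10.T3]}
  - cp_id: 11
    study_id: GSE57468
    platform_id: GPL6885
    context: OCD
    control: {label: "BMM RANKL 2day", samples: [CP11.C1, CP11.C2, CP11.C3]}
    test: {label: "BMM RANKL 0day", samples: [CP11.T1, CP11.T2, CP11.T3]}
  - cp_id: 12
    study_id: GSE57468
    platform_id: GPL6885
    context: OCD
    control: {label: "BMM RANKL 3day", samples: [CP12.C1, CP12.C2, CP12.C3]}
    test: {label: "BMM RANKL 0day", samples: [CP12.T1, CP12.T2, CP12.T3]}
  - cp_id: 13
    study_id: GSE76988
    platform_id: GPL13112
    context: OCD
    control: {label: "wild-type osteoclast M-CSF RANKL 24H", samples: [CP13.C1, CP13.C2, CP13.C3]}
    test: {label: "wild-type osteoclast M-CSF RANKL IL-3 24H", samples: [CP13.T1, CP13.T2, CP13.T3]}
  - cp_id: 14
    study_id: GSE76988
    platform_id: GPL13112
    context: OCU
    control: {label: "wild-type osteoclast precursor M-CSF 24H", samples: [CP14.C1, CP14.C2, CP14.C3]}
    test: {label: "wild-type osteoclast M-CSF RANKL 24H", samples: [CP14.T1, CP14.T2, CP14.T3]}
  - cp_id: 15
    study_id: GSE72846
    platform_id: GPL17021
    context: OCD
    control: {label: "Control", samples: [CP15.C1, CP15.C2, CP15.C3]}
    test: {label: "MMP9 KO", samples: [CP15.T1, CP15.T2, CP15.T3]}
  - cp_id: 16
    study_id: GSE135479
    platform_id: GPL21103
    context: OCU
    control: {label: "RANKL", samples: [CP16.C1, CP16.C2, CP16.C3]}
    test: {label: "FOXO3 RANKL", samples: [CP16.T1, CP16.T2, CP16.T3]}
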