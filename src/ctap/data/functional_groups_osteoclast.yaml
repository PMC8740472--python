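# Curated osteoclast-differentiation functional groups: 14 marker-gene sets,
# each expected to be collectively activated or inhibited depending on whether
# the comparison pair captures up- (OCU) or down- (OCD) regulated
# differentiation.  Genes may recur across groups; each (group, gene) entry is
# a distinct marker slot.
groups:
  - name: "Autoregulatory - up"
    genes: [CCL9, CCR1, CD109, CXCL10, SDC1, VEGFC]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "Cell Differentiation signaling factors - down"
    genes: [PLCB4, PLCB2, GIT1, DOCK5, TRAF1, TRAF6]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "Cell Differentiation"
    genes: [CLCN7, CAR2, CALCR, CSF1R, TREM2, TNFRSF11A, OSCAR, OCSTAMP,
            MST1R, ITGB3, DCSTAMP]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "Cytoskeleton Control"
    genes: [DCSTAMP, LAD1, MYO1B, OCSTAMP, SCIN, MYOD1, MARCKS]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "Integrin Beta3"
    genes: [CLCN7, OCSTAMP, CALCR, MST1R, CTSK, MMP14, ITGB3, MYO1D, ACP5,
            MMP9, CAR2, OSCAR]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "Secreted Factors for External Cells - up"
    genes: [INF2, SEMA4D, SGPL1, SPP1, CXCL10, CCL9]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "Coupling Factors"
    genes: [PGF, SPNS2, CD200, SGPL1, SEMA7A, LIF, CST7]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "ACID & Enzymes for Matrix Dissolution"
    genes: [VCAN, ATP6V0D2, CAR2, CLCN7, SLC9B6, CTSK, ACP5, PDE2A, MMP14,
            HTRA1, MMP9, ADAM10, ATP6V0B, ATP6V0C, ATP6V0C-PS2]
    expected_state: {OCU: Activation, OCD: Inhibition}
  - name: "Autoregulatory - down"
    genes: [C1QA, C1QB, C1QC, CCL2, CCL3, CCL4, CCL6, CCL7, CXCL14, IGFBP4,
            PF4]
    expected_state: {OCU: Inhibition, OCD: Activation}
  - name: "Calcinuren Pathway"
    genes: [CALM1, CAMK1, CAMK2A, CALM2, CALM3, PPP3CA]
    expected_state: {OCU: Inhibition, OCD: Activation}
  - name: "Cell Differentiation signaling factors - up"
    genes: [PPP2R3A, PPP3CA, CALM2, PPP2R3C, CAMK1, TNFAIP2, CAMK2A, CALM3,
            CALM1]
    expected_state: {OCU: Inhibition, OCD: Activation}
  - name: "Cell Signaling"
    genes: [SLIT1, SGPL1, INFB, IL10, CXCL5, IGF1, SPP1, SLIT3, C1QA, CCL8,
            CCL7, C1QC, C1QB]
    expected_state: {OCU: Inhibition, OCD: Activation}
  - name: "MSC Signature"
    genes: [ACTA2, ACTG2, BGN, CCND1, COL1A1, COL1A2, COL2A1, DKK3, FN1,
            SERPINH1, SPARC, TNC]
    expected_state: {OCU: Inhibition, OCD: Activation}
  - name: "Secreted Factors for External Cells - down"
    genes: [CCL6, CCL4, CCL3, CCL2, C1QC, C1QB, CCL7, CXCL14, CD200R1,
            CXCL16, IGF1, APOE, C1QA]
    expected_state: {OCU: Inhibition, OCD: Activation}
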