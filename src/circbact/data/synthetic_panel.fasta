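;; SYNTHETIC reference panel.
;; These are synthetic stand-in mature cores patterned on the circular
;; bacteriocin family (AS-48-like length, helical hydrophobic composition,
;; L/V/W N-terminus and W/Y/F C-terminus for the circular entries).  They
;; are NOT the published records; substitute a curated FASTA of real mature
;; cores via --panel / ReferencePanel.from_fasta for production mining.
>syn_as48_like type=circular len=70
LAGKFGIPAVVAGTVLNVGEAGGAVTTIVSILTAVGSGGLSLFAAAGRESIRQYMKNEIKKRGKKAVIAW
>syn_pumilarin_like type=circular len=70
LSKTLGISSAAGTVLDAMKGFASGGAWALTTGVSLIAPAGKEQIKKYLKNEIKKKGRKAVLDFIGNAAMW
>syn_amylocyclicin_like type=circular len=64
VAGGLMNVAQHAGSLAGPVAKGAMTGINTLGSFNLGQIAGSTLGVAKGSAEVFSKHAGSIGTKF
>syn_nkr53b_like type=circular len=64
WGSNLGNALGSVAKGALTFASPYLEKHGAQGVSAMNGLVDRTAKELGIHLPVAFSAMETGKSLY
>syn_closticin_like type=linear len=82
MKDNAELFTGAVQKVGQSIGKLFKNGAIRDASELTLDQNGWSTVAQGFAKGAIDGNSFTQSLLGKAHDVGMGAIHDLNSAFY
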