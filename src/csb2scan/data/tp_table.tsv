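# Termination-product percentages (TP%) printed in the running text of the
# source transcription study; matrix heat-map values are not reproduced here.
# Non-tract constructs: G>A = G-tract replaced by adenines (basal T-tract
# stalling); dTP = downstream T-tract deleted; A6 = T-tract mutated to an
# A6 run; (UC)3 = alternate thymines changed to cytosine.
variant	mean_tp	sd	n	provenance
G5AG7	17		3	in vitro run-off transcription, mini-gel TP quantification (triplicate)
G7AG6	17		3	in vitro run-off transcription, mini-gel TP quantification (triplicate)
G3AG9	11		3	in vitro run-off transcription, mini-gel TP quantification (triplicate)
G>A	9		3	basal T-tract stalling, G-tract replaced by adenines (triplicate)
G>A_dTP	6		3	non-specific background, G-tract and T-tract both removed (triplicate)
dTP	10		3	downstream T-tract deletion (triplicate)
A6	10		3	T-tract mutated to A6 run (triplicate)
(UC)3	13		3	alternate T>C substitutions in the T-tract (triplicate)
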