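# Published model-validation metrics across display configurations and
# perturbation directions: average error (sway deg, COP cm) and zero-lag
# cross-correlation, per axis (AP/ML) and perturbation direction (deg).
# Structural gaps (configurations not evaluated) are absent rows.
metric,display,axis,direction_deg,value
sway_avg_error_deg,off,AP,180,0.16
sway_avg_error_deg,off,AP,225,0.19
sway_avg_error_deg,off,ML,225,0.09
sway_avg_error_deg,off,ML,90,0.19
sway_avg_error_deg,1x2,AP,180,0.85
sway_avg_error_deg,1x2,AP,225,0.27
sway_avg_error_deg,1x2,ML,225,0.11
sway_avg_error_deg,3x4,AP,180,0.33
sway_avg_error_deg,3x4,AP,225,0.36
sway_avg_error_deg,3x4,ML,225,0.10
sway_avg_error_deg,3x4,ML,90,0.18
sway_avg_error_deg,3x8,AP,225,0.21
sway_avg_error_deg,3x8,ML,225,0.14
sway_avg_error_deg,3x16,AP,225,0.30
sway_avg_error_deg,3x16,ML,225,0.12
sway_xcorr,off,AP,180,0.998
sway_xcorr,off,AP,225,0.99
sway_xcorr,off,ML,225,0.97
sway_xcorr,off,ML,90,0.95
sway_xcorr,1x2,AP,180,0.94
sway_xcorr,1x2,AP,225,0.97
sway_xcorr,1x2,ML,225,0.98
sway_xcorr,3x4,AP,180,0.98
sway_xcorr,3x4,AP,225,0.95
sway_xcorr,3x4,ML,225,0.98
sway_xcorr,3x4,ML,90,0.96
sway_xcorr,3x8,AP,225,0.98
sway_xcorr,3x8,ML,225,0.95
sway_xcorr,3x16,AP,225,0.97
sway_xcorr,3x16,ML,225,0.93
cop_avg_error_cm,off,AP,180,0.47
cop_avg_error_cm,off,AP,225,0.21
cop_avg_error_cm,off,ML,225,0.33
cop_avg_error_cm,off,ML,90,0.46
cop_avg_error_cm,1x2,AP,180,0.49
cop_avg_error_cm,1x2,AP,225,0.26
cop_avg_error_cm,1x2,ML,225,0.51
cop_avg_error_cm,3x4,AP,180,0.46
cop_avg_error_cm,3x4,AP,225,0.23
cop_avg_error_cm,3x4,ML,225,0.51
cop_avg_error_cm,3x4,ML,90,0.42
cop_avg_error_cm,3x8,AP,225,0.34
cop_avg_error_cm,3x8,ML,225,0.49
cop_avg_error_cm,3x16,AP,225,0.27
cop_avg_error_cm,3x16,ML,225,0.42
cop_xcorr,off,AP,180,0.98
cop_xcorr,off,AP,225,0.99
cop_xcorr,off,ML,225,0.98
cop_xcorr,off,ML,90,0.98
cop_xcorr,1x2,AP,180,0.97
cop_xcorr,1x2,AP,225,0.98
cop_xcorr,1x2,ML,225,0.93
cop_xcorr,3x4,AP,180,0.96
cop_xcorr,3x4,AP,225,0.99
cop_xcorr,3x4,ML,225,0.93
cop_xcorr,3x4,ML,90,0.98
cop_xcorr,3x8,AP,225,0.97
cop_xcorr,3x8,ML,225,0.92
cop_xcorr,3x16,AP,225,0.98
cop_xcorr,3x16,ML,225,0.95
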