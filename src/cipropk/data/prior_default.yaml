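# Default log-normal population prior for the MAP-Bayesian individual fits.
#
# These central values are the cohort's own individual-analysis medians
# (CL 18.59 L/h, Vd 136.9 L) with a conservative 50% CV.  Users who want to
# reproduce the behaviour of TDM software initialised from the Drusano et al.
# ciprofloxacin population should substitute that literature prior here; it
# is deliberately not hard-coded in this package.
cl: 18.59      # L/h
vd: 136.9      # L
cv_cl: 0.5     # log-scale SD (~CV); null for a flat prior
cv_vd: 0.5
source: cohort-medians-50cv
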