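"""A small replicate comparison study: Bayesian selections vs voting.

Runs three replicates of the score-mis-specification scenario (scores
swap Gaussian components with probability 0.10) at reduced size, and
prints the study table: predicted precision (1 - estimated FDR),
empirical precision, recall and F1 for single tools, the Bayesian
selections and the two voting baselines.  For the full-size published
tables use `svbayes study --case 2 --replicates 10 --seed 1 --out-dir out`.
"""

from svbayes import McmcConfig, replicate_study, summarize_study

table = replicate_study(
    2, n_reps=3, n=1000, seed=11,
    mcmc=McmcConfig(iterations=2000, burn_in=800, n_chains=1),
)
summary = summarize_study(table)
print(summary.round(3).to_string())
print("\nNote the tool rows: predicted precision sits below the empirical "
      "precision because the mis-specified scores bias the FDR estimates, "
      "yet the Bayesian selections still beat both voting baselines on F1.")
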