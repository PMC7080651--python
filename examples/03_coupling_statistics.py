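"""The core within-subject statistic: median split and Spearman→Fisher z.

For one subject, trials in each congruency condition are split into fast
and slow bins at the median RT; the mean prestimulus alpha power per bin
and the Fisher-transformed Spearman correlation between single-trial alpha
power and RT summarize how strongly preparatory alpha states modulate
response speed.
"""

from alphacoupling import (
    SimulationParams,
    exclude_trials,
    median_split,
    prestimulus_alpha_power,
    simulate_subject,
    subject_coupling,
)
from alphacoupling.pipeline import PipelineConfig, process_subject

# strong coupling + low noise so the structure is visible at a glance
params = SimulationParams(
    trials_per_condition=60,
    coupling_rho={"HC": 0.5, "MCI": 0.0},
    noise_amp=0.5,
)
rec = simulate_subject(params, "HC", subject_seed=4, subject_id="demo")
table, _ = process_subject(rec, PipelineConfig(simulation=params))

out = subject_coupling(table, subject="demo", group="HC")
print(out[["condition", "n_trials", "alpha_fast", "alpha_slow",
           "alpha_diff", "rho", "z"]].round(3).to_string(index=False))
print(
    "\nalpha_diff > 0: lower prestimulus alpha preceded faster responses;\n"
    "z is the Fisher transform 0.5*ln((1+rho)/(1-rho)) of the per-subject\n"
    "Spearman correlation (generative target here: rho = 0.5, attenuated\n"
    "by background EEG noise)."
)
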