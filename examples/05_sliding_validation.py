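"""Calendar-ordered sliding validation over a simulated 12-session scenario.

Session order matters for unit tracking (drift accumulates), so validation
slides a contiguous window over the sessions: each window trains on its
leading block and tracks its trailing block.  Prints the per-window metric
table and the mean +/- SD summary.
"""

from spiketrack.evaluation import ValidationPlan, sliding_validation
from spiketrack.synthetic import ScenarioConfig, generate_scenario
from spiketrack.tracker import TrackerConfig

cfg = ScenarioConfig(channels=8, days=12, duration=300.0, seed=5)
sessions, truth = generate_scenario(cfg)

plan = ValidationPlan(dataset_count=12, window_count=3, train_size=4, test_size=5)
configs = [
    TrackerConfig(strategy=s, feature_set_id=4, classifier="RVM")
    for s in ("FMD", "MMD")
]
table, summary = sliding_validation(sessions, truth, plan, configs, seed=0)
print(table.to_string(index=False))
print()
print(summary.to_string(index=False))
print("\neach row of the first table is one window x configuration run;")
print("the summary aggregates windows (mean and SD, the error bars one")
print("would plot when comparing classifiers and strategies).")
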