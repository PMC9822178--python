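"""Show the accuracy gain from fusing independent noisy classifiers.

Three conditionally independent mock classifiers, each 70% accurate with a
symmetric confusion matrix, classify 5,000 simulated records. Fusing their
probability outputs with Dempster's rule beats every individual model —
the ensemble analogue of majority voting, but weighted by each model's
per-record confidence.
"""

from sentifuse import (
    MockParams,
    SimulationConfig,
    simulate_corpus,
    simulate_ensemble_outputs,
    sweep_combinations,
)

cfg = SimulationConfig(n_pre=2500, n_peri=2500, seed=7)
corpus = simulate_corpus(cfg, with_text=False)
mocks = [MockParams.symmetric(0.7, seed=i) for i in range(3)]
tables = simulate_ensemble_outputs(corpus, mocks, seed=7)
gold = {r.id: r.gold_label for r in corpus}

report = sweep_combinations(tables, gold, [["model1", "model2", "model3"]])
print(report.to_string(index=False))
print()
print("Each model alone sits near its configured 70% accuracy; the DST")
print("fusion of all three reaches ~80% — independent errors cancel when")
print("the evidence is multiplied and renormalised.")
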