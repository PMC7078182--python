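"""Sweep fertility and trace the clustering transition against λ.

Runs a small paired sweep (same kin network and traits for all three
algorithms at each replicate), then asks whether the χ-vs-λ curve is u-shaped
per algorithm. Under homophilic choice clustering falls as relatives grow
scarce but recovers once most contacts are chosen friends; under random
choice it only falls.
"""

from homophilynet import detect_ushape, plot_transition, reduced_scale_config, run_sweep

config = reduced_scale_config(base_seed=3, replicates_per_level=3)
result = run_sweep(config)

for algorithm in config.algorithms:
    d = detect_ushape(result.for_algorithm(algorithm))
    verdict = "u-shaped" if d["is_ushaped"] else "not u-shaped"
    print(f"{algorithm:>9}: {verdict:>12}, trough at lambda={d['trough_lambda']:.2f}")

plot_transition(result, "transition.png")
print("wrote transition.png (chi vs lambda, one colour per algorithm)")
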