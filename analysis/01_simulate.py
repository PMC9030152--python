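#!/usr/bin/env python
"""Generate the synthetic study cohort with planted ground truth.

Writes every input table the downstream analyses consume (alteration calls,
sample annotations, IHC levels, two dependency screens, scored PPI edges,
functional network, complex catalog, gene sets, truth) to
results/synthetic/.
"""

from pathlib import Path

from rbprior.synthetic import SimulationConfig, simulate_all, write_all

OUT = Path(__file__).resolve().parents[1] / "results" / "synthetic"


def main() -> None:
    config = SimulationConfig(seed=1)
    bundle = simulate_all(config)
    write_all(bundle, OUT)
    truth = bundle["truth"]
    print(f"cohort: {config.n_patients} patients, {len(bundle['alterations'])} alteration calls")
    print(f"planted progressors: {', '.join(sorted(truth.planted_progressors))}")
    print(f"planted suppressors: {', '.join(sorted(truth.planted_suppressors))}")
    print(f"planted complex size: {len(truth.planted_complex)}")
    print(f"tables written to {OUT}")


if __name__ == "__main__":
    main()
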