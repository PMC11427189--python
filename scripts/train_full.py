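"""Opt-in full-scale training run: 12 modes, 40,000 episodes.

Reproduces the full study conditions — N = 12 target modes (Noll 4-15),
uniform +-0.15-um training aberrations plus higher-order noise, 0.5-um
observation bias, 15 exploration profiles per episode, 4,000 warm-up
episodes — on the default 128-px simulator, then benchmarks the trained
agent against parabolic maximization under configurations A/B/C (1,000
trials each).  The configuration-C comparison point is a mean residual of
0.023 um RMS.  Expect many hours on one CPU; this script is not part of
the test suite.

Usage:
    python scripts/train_full.py --seed 0 --outdir results/full_run
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np

import saoslo as s
from saoslo.agent import TrainingSchedule


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--episodes", type=int, default=40_000)
    ap.add_argument("--outdir", type=Path, default=Path("results/full_run"))
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    system = s.default_system()
    env = s.SAOEnv(system, "train_uniform", bias=0.5, seed=args.seed)
    schedule = TrainingSchedule(episodes=args.episodes, seed=args.seed)
    checkpoint, trace = s.train(env, schedule, progress=True)
    checkpoint.save(args.outdir / "agent")
    trace.to_csv(args.outdir / "trace.csv", index=False)

    summary = {}
    for config in ("A", "B", "C"):
        for method in ("agent", "parabolic"):
            st = s.run_benchmark(method, config, 1000, args.seed + 1,
                                 system=system, bias=0.2,
                                 checkpoint=checkpoint)
            summary[f"{method}_{config}"] = st.summary()
            print(f"{method} config {config}: mean RMS-WFE "
                  f"{st.mean:.4f} um (sd {st.sd:.4f})")
    (args.outdir / "benchmark.json").write_text(json.dumps(summary, indent=2))


if __name__ == "__main__":
    main()
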