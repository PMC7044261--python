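"""Simulate the AM depth-discrimination experiment at study scale.

Six synthetic listeners, three staircase-pair repetitions per cell,
ground truth = the weak-suppression gain-control parameters (omega =
0.02).  Prints the binaural summation at detection threshold and the
monaural:binaural threshold ratio above threshold, and writes
results/dipper_thresholds.csv (+ the full trial log).
"""

import pathlib

import numpy as np

from binsum.observer import PEDESTALS
from binsum.pipeline import RunConfig, run_simulate_psychophysics

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
SEED = 11


def main() -> None:
    cfg = RunConfig(mode="simulate-psychophysics", seed=SEED, out_dir=str(OUT),
                    fixture="6a", n_participants=6, n_reps=3, overwrite=True)
    ds = run_simulate_psychophysics(cfg)

    det_pooled = ds.threshold("mon", 0.0)   # pooled mon/dich/half_bin detection
    det_bin = ds.threshold("bin", 0.0)
    summation_db = det_pooled - det_bin
    print(f"detection thresholds: monaural-type {det_pooled:.2f} dB, "
          f"binaural {det_bin:.2f} dB")
    print(f"binaural summation at detection: {summation_db:.2f} dB "
          f"(factor {10 ** (summation_db / 20):.2f})")

    ratios = [
        ds.threshold("mon", P) - ds.threshold("bin", P) for P in PEDESTALS[1:]
    ]
    print(f"mon - bin separation above threshold: mean {np.mean(ratios):.2f} dB "
          f"(factor {10 ** (np.mean(ratios) / 20):.2f}); "
          f"separation persists at the highest pedestals "
          f"({ratios[-1]:.2f} dB @ 64%)")
    bin_db = [ds.threshold("bin", P) for P in PEDESTALS]
    dip = PEDESTALS[int(np.argmin(bin_db))]
    print(f"binaural dipper: detection {det_bin:.1f} dB, dip bottom at "
          f"pedestal {dip:g}% ({min(bin_db):.1f} dB), masking handle rises to "
          f"{bin_db[-1]:.1f} dB @ 64%")
    print(f"wrote {OUT / 'dipper_thresholds.csv'}")


if __name__ == "__main__":
    main()
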