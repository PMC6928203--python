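"""The full synthetic cohort study: EPI-like warp vs RARE-like blur.

Seven kidney phantoms (per-subject anatomy and per-layer D variation)
are imaged under both conditions at SNR 50, segmented, fitted and
summarised. Reports the per-condition border-displacement medians with
ranges, the exact Mann–Whitney comparison, the fold-difference, and the
per-layer variability comparison. Full report (JSON + CSV + example
maps) goes to results/cohort/.
"""

import warnings
from pathlib import Path

from renaldwi import CohortConfig, run_cohort_experiment
from renaldwi.stats import summarize_group

OUT = Path(__file__).resolve().parents[1] / "results" / "cohort"
SEED = 20240904


def main() -> None:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rep = run_cohort_experiment(CohortConfig(seed=SEED), out_dir=OUT)

    for cond, s in rep["bd_summary"].items():
        print(f"border displacement, {cond}: "
              f"{summarize_group(s['values']).render()}")
    mw = rep["mann_whitney_bd"]
    print(f"exact Mann-Whitney: U = {mw['U']:.0f}, "
          f"p = {mw['p_two_sided']:.4g} ({mw['method']})")
    cmpbd = rep["bd_comparison"]
    print(f"fold-difference of BD medians: {cmpbd['fold_difference']:.1f} "
          f"({cmpbd['median_a']:.2f} vs. {cmpbd['median_b']:.2f})")
    print("\nintra-subject variability (SD/mean over layer ROI means):")
    for lay, c in rep["variability_comparison"].items():
        print(f"  {lay}: warped {c['median_a']:.3f} vs. blurred "
              f"{c['median_b']:.3f} ({c['percent_excess']:+.0f}%)")
    print(f"\nwrote report to {OUT}")


if __name__ == "__main__":
    main()
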