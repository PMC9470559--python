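"""Full trial analysis over a cohort directory (default: the packaged
reference cohort).

Derives every endpoint, applies the two-stage decision rule and the
design-adjusted inference, and writes the JSON trial report.  On the
reference cohort this reproduces the published aggregates: 7/20 improved
(35.0%), none worsened, estimate 32.8% [80% CI 20.7%, 46.7%], p =
3.395e-5, 15/20 with any length reduction, 7/17 (41.2%) with less
extensive surgery than planned.

Usage: python analysis/04_trial_report.py [--cohort DIR] [--out results/trial_report.json]
"""

import argparse
import sys
from importlib import resources
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from vttrial.cohort import read_cohort, reference_cohort
from vttrial.pipeline import TrialConfig, run_trial_analysis


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cohort", type=Path, default=None, help="cohort directory (CSVs)")
    ap.add_argument("--out", type=Path, default=Path("results/trial_report.json"))
    args = ap.parse_args()

    cohort = read_cohort(args.cohort) if args.cohort else reference_cohort()
    report = run_trial_analysis(cohort, TrialConfig())

    p = report.primary
    inf = p["inference"]
    print(
        f"primary: {p['improved']}/{p['evaluable']} improved "
        f"({p['proportion_improved_pct']}%), {p['worsened']} worsened; "
        f"trial {'SUCCESS' if p['trial_success'] else 'FAILURE'}"
    )
    print(
        f"inference: estimate {inf['estimate_pct']}% "
        f"[{inf['ci_lower_pct']}%, {inf['ci_upper_pct']}%], p = {inf['p_value']:.4g}"
    )
    s = report.secondary
    print(
        f"secondary: {s['any_length_reduction']['count']}/{s['any_length_reduction']['n']} "
        f"any length reduction; VTT-PR {s['vtt_pr']['count']}/{s['vtt_pr']['n']}; "
        f"surgery less extensive {s['surgical_change']['less_extensive']}"
        f"/{s['surgical_change']['n_operated']} "
        f"({s['surgical_change']['less_extensive_pct']}%)"
    )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(report.to_json() + "\n")
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
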