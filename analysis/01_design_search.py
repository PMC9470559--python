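"""Search for the two-stage design behind the trial's statistical plan.

Enumerates every Simon two-stage design up to the search ceiling for the
stated error specification (5% unacceptable vs 25% target response rate,
one-sided alpha 0.10, power 0.90) and reports the minimax and optimal
designs with their exact operating characteristics.

Finding: the minimax design is (r1=0, n1=13, r=2, n=20) — stop if none of
the first 13 patients improves, call the trial a success on >= 3 total
improvements — with attained alpha 7.4% and power 90.3%.

Usage: python analysis/01_design_search.py [--p0 0.05 --p1 0.25 ...]
"""

import argparse
import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from vttrial.design import DesignSpec, search_designs


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--p0", type=float, default=0.05)
    ap.add_argument("--p1", type=float, default=0.25)
    ap.add_argument("--alpha", type=float, default=0.10)
    ap.add_argument("--beta", type=float, default=0.10)
    ap.add_argument("--n-max", type=int, default=60)
    ap.add_argument("--out", type=Path, default=Path("results/design.json"))
    args = ap.parse_args()

    spec = DesignSpec(args.p0, args.p1, args.alpha, args.beta, args.n_max)
    results = search_designs(spec)

    payload = {}
    for kind, (design, props) in results.items():
        payload[kind] = {
            "r1": design.r1,
            "n1": design.n1,
            "r": design.r,
            "n": design.n,
            "attained_alpha": round(props.attained_alpha, 6),
            "attained_power": round(props.attained_power, 6),
            "pet_p0": round(props.pet_p0, 6),
            "expected_n_p0": round(props.expected_n_p0, 3),
        }
        print(
            f"{kind:8s} r1/n1 = {design.r1}/{design.n1}, r/n = {design.r}/{design.n}  "
            f"alpha = {props.attained_alpha:.4f}, power = {props.attained_power:.4f}, "
            f"PET(p0) = {props.pet_p0:.3f}, EN(p0) = {props.expected_n_p0:.2f}"
        )

    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {args.out}")
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
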