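"""Deterministic expected-gain profiles: how the predicted benefit of a
combined reference moves with foreign reference size, genetic
correlation and proof reliability.

Pure closed-form analysis (no simulation): anchors M_e to a typical
national reliability, then sweeps one factor at a time. Writes
results/expected_gain_profiles.csv.
"""

import argparse
import pathlib

import pandas as pd

from gpcombine import ExpectedGainInputs, Source, calibrate_me, expected_reliability

NATIONAL = dict(n=3500, rel=0.85)
ANCHOR_REL = 0.45  # typical national validation reliability


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", default="results")
    args = ap.parse_args()
    out = pathlib.Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    nat = ExpectedGainInputs(sources=[Source(NATIONAL["n"], NATIONAL["rel"])])
    me = calibrate_me(ANCHOR_REL, nat)
    r_nat = expected_reliability(nat, me)

    rows = []
    for rg in (0.57, 0.70, 0.88, 0.98):
        for n_foreign in (3000, 6000, 9000, 12000):
            for rel_f in (0.5, 0.7, 0.85):
                comb = ExpectedGainInputs(
                    sources=nat.sources + [Source(n_foreign, rel_f, rg)]
                )
                r = expected_reliability(comb, me)
                rows.append(
                    {"rg": rg, "n_foreign": n_foreign, "rel_foreign": rel_f,
                     "expected_rel": r, "expected_gain": r - r_nat}
                )
    df = pd.DataFrame(rows)
    df.to_csv(out / "expected_gain_profiles.csv", index=False)

    print(f"M_e calibrated to national REL {ANCHOR_REL} at "
          f"N={NATIONAL['n']}, rel={NATIONAL['rel']}: M_e = {me:.0f}")
    print(f"national deterministic reliability: {r_nat:.3f}\n")
    piv = df[df["rel_foreign"] == 0.7].pivot(index="rg", columns="n_foreign",
                                             values="expected_gain")
    print("expected gain (foreign rel 0.7) by rg × foreign reference size:")
    print(piv.round(3).to_string())
    print("\ngain rises with every factor; a low-rg trait (fertility-like, "
          "0.57–0.70) profits least from the same foreign bulls.")


if __name__ == "__main__":
    main()
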