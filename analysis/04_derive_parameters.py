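"""Derive the full pharmacokinetic parameter table from the fits.

Combines each group's dose record with its fitted macro-constants and hybrid
moments to produce the standard parameter set (ClT, Kel, T1/2, MRT in both
elimination-limit and model-free forms, Vd(c), Vd(β), Vd(extrap)).

Outputs: results/pk_parameters.csv (one row per group, full precision).
"""
import argparse
import json
import sys
from pathlib import Path

import pandas as pd

from noncanon_pk.compartmental import MacroConstants
from noncanon_pk.io import read_dose_config
from noncanon_pk.pkparams import derive_parameters

ROOT = Path(__file__).resolve().parents[1] / "results"


def main(argv=None) -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fits", type=Path, default=ROOT / "fits.json")
    ap.add_argument("--dataset", type=Path, default=ROOT / "dataset")
    ap.add_argument("--out", type=Path, default=ROOT / "pk_parameters.csv")
    args = ap.parse_args(argv)

    fits = json.loads(args.fits.read_text())
    doses = read_dose_config(args.dataset / "doses.yaml")
    rows = []
    for group, fit in fits.items():
        macro = MacroConstants(**fit["macro"]) if fit["macro"]["A"] > 0 else MacroConstants(
            A=0.0, B=fit["macro"]["B"], alpha=0.0, beta=fit["macro"]["beta"]
        )
        pk = derive_parameters(
            doses[group], macro,
            auc0_inf=fit["auc0_inf"], aumc0_inf=fit["aumc0_inf"],
            cmax=fit["cmax"], tmax=fit["tmax"],
        )
        rows.append({"group": group, **pk.as_dict()})
    df = pd.DataFrame(rows).set_index("group")
    df.to_csv(args.out)
    print(df.round(3).to_string())
    print(f"wrote {args.out}")


if __name__ == "__main__":
    sys.exit(main())
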