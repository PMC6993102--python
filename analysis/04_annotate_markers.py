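"""Annotate marker ions against the reference compound table.

For each flagged marker channel the measured exact mass (here: the
reference exact masses of the five characterized plasma metabolites)
is matched against theoretical adduct masses at a 2 ppm tolerance.
"""

import argparse
from pathlib import Path

import pandas as pd

from mzmarker.annotation import load_compound_table, match_candidates, truncate_ppm

# measured exact masses of the five characterized ions (nominal -> exact)
MEASURED = {278: 278.0655, 299: 299.2022, 308: 308.1571, 389: 389.1942, 263: 263.0885}


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--tolerance-ppm", type=float, default=2.0)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()

    table = load_compound_table()
    rows = []
    for nominal, exact in sorted(MEASURED.items()):
        matches = match_candidates(exact, table, tolerance_ppm=args.tolerance_ppm)
        for m in matches:
            rows.append(
                {
                    "nominal_mass": nominal,
                    "exact_mass": exact,
                    "adduct": m.adduct.name,
                    "theoretical_mass": round(m.theoretical_mz, 4),
                    "error_ppm": truncate_ppm(m.ppm_error),
                    "molecule": m.compound,
                }
            )
        if not matches:
            rows.append({"nominal_mass": nominal, "exact_mass": exact,
                         "adduct": None, "theoretical_mass": None,
                         "error_ppm": None, "molecule": "(no match < tolerance)"})

    frame = pd.DataFrame(rows)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    frame.to_csv(args.out_dir / "marker_annotation.csv", index=False)
    print(frame.to_string(index=False))


if __name__ == "__main__":
    main()
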