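"""Regenerate the embedded elemental cross-section CSV resources.

The tables are fully determined by the analytic models in
``straydose.physics``; this script exists so the shipped files can be audited
and rebuilt (``python scripts/make_xs_tables.py``).
"""

import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from straydose.physics import ELEMENTS, generate_element_table  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "src" / "straydose" / "data" / "xs"


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    for symbol in ELEMENTS:
        arr = generate_element_table(symbol)
        path = OUT / f"{symbol}.csv"
        with open(path, "w") as fh:
            fh.write("energy_mev,pe,incoherent,pair\n")
            for row in arr:
                fh.write("%.8e,%.8e,%.8e,%.8e\n" % tuple(row))
        print(f"wrote {path} ({len(arr)} rows)")


if __name__ == "__main__":
    main()
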