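"""Regenerate the shipped elastic-score background calibration table.

Run from the repository root:  python scripts/build_calibration.py
"""
import sys

from tmic7.distscore import calibrate_background
from tmic7.synthetic_data import make_decoys


def main(seed: int = 20230220) -> None:
    decoys = make_decoys(120, (100, 600), seed=seed)
    cal = calibrate_background(decoys, seed=seed, max_pairs=1000)
    cal.to_table("src/tmic7/data/calibration.tsv")
    print("wrote src/tmic7/data/calibration.tsv "
          f"(decoys={cal.decoy_count}, bins={len(cal.sizes)})")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20230220)
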