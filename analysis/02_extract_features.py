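#!/usr/bin/env python
"""Extract radiomic features from the simulated B-scans written by step 01.

Reads the 8-bit PNGs + mask PNGs back from disk (mirroring the
JPG-era workflow where feature math sees quantized intensities) and
computes the reduced filter profile (original + wavelet subbands; all
first-order/texture families + shape) — 474 features per eye.
"""

import argparse
from dataclasses import dataclass
from pathlib import Path

from octomics.features import BScanImage, ExtractionConfig, ROIMask, extract_table
from octomics.io import read_image_png, read_mask_png

ROOT = Path(__file__).resolve().parents[1]


@dataclass
class _Eye:
    eye_id: str
    image: BScanImage
    mask: ROIMask


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--full-profile", action="store_true",
                    help="all 13 derived images (1218 features); ~8x slower")
    args = ap.parse_args()

    img_dir = ROOT / "scratch" / f"cohort_seed{args.seed}"
    if not img_dir.exists():
        raise SystemExit(f"{img_dir} missing - run 01_simulate_cohort.py first")
    eyes = []
    for p in sorted((img_dir / "images").glob("*.png")):
        eyes.append(_Eye(eye_id=p.stem,
                         image=read_image_png(p),
                         mask=read_mask_png(img_dir / "masks" / p.name)))
    cfg = ExtractionConfig() if args.full_profile else ExtractionConfig.fast()
    table = extract_table(eyes, cfg)
    out = ROOT / "results" / "analysis"
    out.mkdir(parents=True, exist_ok=True)
    table.to_csv(out / "features.csv")
    print(f"extracted {table.shape[1]} features for {table.shape[0]} eyes "
          f"-> {out/'features.csv'}")


if __name__ == "__main__":
    main()
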