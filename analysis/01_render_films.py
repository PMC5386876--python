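#!/usr/bin/env python
"""Render a batch of synthetic pupal films with ground truth.

Films emulate backlit transparency photographs: dark capsule-shaped pupae
(half placed in touching clusters) plus the 16.25 mm calibration coin.
Images go to scratch/films/ (binary artefacts); the ground-truth tables,
which downstream scripts compare against, go to results/films/.
"""

from pathlib import Path

from pupastat.synth import SimImageConfig, render_film

ROOT = Path(__file__).resolve().parents[1]
IMG_DIR = ROOT / "scratch" / "films"
TRUTH_DIR = ROOT / "results" / "films"
N_FILMS = 6
SEED0 = 500

if __name__ == "__main__":
    IMG_DIR.mkdir(parents=True, exist_ok=True)
    TRUTH_DIR.mkdir(parents=True, exist_ok=True)
    cfg = SimImageConfig(n_pupae=60, touch_prob=0.5)
    for i in range(N_FILMS):
        stem = f"film_{i:02d}"
        _, truth = render_film(
            cfg, seed=SEED0 + i,
            image_out=IMG_DIR / f"{stem}.png",
            truth_out=TRUTH_DIR / f"{stem}_truth.csv")
        print(f"{stem}: {len(truth)} pupae, "
              f"mean true length {truth['length_mm'].mean():.3f} mm")
    print(f"wrote {N_FILMS} films to {IMG_DIR} (truth in {TRUTH_DIR})")
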