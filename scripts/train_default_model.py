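#!/usr/bin/env python
"""Regenerate the packaged default model from the synthetic generator.

The shipped ``src/even/data/default_model.json`` was produced by this
script.  It trains the discriminant on a seeded 40 good + 40 bad synthetic
set and records grouped 5-fold cross-validation results plus provenance
metadata (``training_data: synthetic``).
"""

from pathlib import Path

from even.classify import cross_validate, save_model, train_lda
from even.simulate import build_training_set

SEED = 20260901
OUT = Path(__file__).resolve().parent.parent / "src/even/data/default_model.json"


def main() -> None:
    X, y, g = build_training_set(40, 40, seed=SEED)
    model = train_lda(X, y)
    cv = cross_validate(X, y, g, seed=SEED)
    model.metadata.update({
        "training_data": "synthetic",
        "description": (
            "Fitted on 40 good + 40 bad seeded synthetic blob phantoms "
            "(8x8 grid of 64px tiles, Gaussian-mask degradation model). "
            "Not trained on experimental data; retrain for quantitative work."
        ),
        "n_good": 40,
        "n_bad": 40,
        "seed": SEED,
        "cv": {k: v for k, v in cv.items() if k.startswith("mean_")},
    })
    save_model(model, OUT)
    print(f"wrote {OUT}")
    print("good-direction coefficients:",
          dict(zip(model.feature_names, model.good_direction())))


if __name__ == "__main__":
    main()
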