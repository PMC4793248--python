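"""Regenerate the frozen (intercept, scale) constants of the default scenarios.

For each scenario the treatment linear predictor is ``intercept + scale *
base(W)`` with a shared coefficient direction; the two free parameters are
solved exactly so that the extreme true propensities over 10^6 reference
covariate draws (seed ``CALIBRATION_SEED``) hit the scenario's target range.
The printed mapping is pasted into ``attmatch.synthetic._CALIBRATED``.

Run from the repository root:

    python scripts/calibrate_scenarios.py
"""

from attmatch.synthetic import (
    CALIBRATION_SEED,
    SUPPORT_TARGETS,
    calibrate_scale,
)


def main() -> None:
    print(f"calibration seed: {CALIBRATION_SEED}")
    print("_CALIBRATED = {")
    for name, (lo, hi) in SUPPORT_TARGETS.items():
        intercept, scale = calibrate_scale(lo, hi)
        print(f"    {name!r}: ({intercept!r}, {scale!r}),")
    print("}")


if __name__ == "__main__":
    main()
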