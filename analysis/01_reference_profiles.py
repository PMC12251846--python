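"""Build the severity-specific reference inhalation profiles.

Writes the condensed 18-point moderate and severe COPD reference curves as
two-column CSVs and prints their headline geometry (PIF, time-to-PIF,
inhaled volume).  These curves are the fixed anchors of the training
simulation: every simulated inhalation is a slope-perturbed version of one
of them, and only the volume *relative* to the reference enters the model.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from inhalersim.config import load_run_config
from inhalersim.profiles import build_reference_profile, inhaled_volume

OUT = Path(__file__).resolve().parents[1] / "results" / "profiles"


def main() -> None:
    config = load_run_config()
    OUT.mkdir(parents=True, exist_ok=True)
    for severity, spec in config.profiles.items():
        curve = build_reference_profile(spec)
        path = OUT / f"reference_profile_{severity}.csv"
        curve.to_csv(path)
        print(
            f"{severity:9s}  PIF {curve.pif:5.1f} L/min at {curve.time_to_pif:.2f} s, "
            f"duration {curve.times[-1]:.2f} s, inhaled volume {inhaled_volume(curve):.3f} L"
            f"  -> {path.relative_to(OUT.parents[1])}"
        )
    print("\nThe severe profile is sharper and stronger than the moderate one; "
          "the simulation only ever compares each simulated volume with its own "
          "severity's reference, so absolute calibration of these synthetic "
          "stand-ins is not required.")


if __name__ == "__main__":
    main()
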