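#!/usr/bin/env python
"""Super-resolution rendering of a synthetic filopodial shaft.

Accumulates localizations drawn at the measured 116.5 nm transverse
confinement onto the 16x canvas (6.25 nm pitch, displayed ~6.3 nm) and
measures the profile FWHM in both the super-resolution and the
diffraction-limited channel (PSF set for a 357 nm convolved width).
Writes the measurements to results/superres/.
"""

import json
from pathlib import Path

from filotrack import benchmarks
from filotrack.superres import SuperResCanvas

OUT = Path(__file__).resolve().parent.parent / "results" / "superres"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    sr, dl = benchmarks.superres_fwhm_recovery(seed)
    canvas = SuperResCanvas(8, 8, 100.0)
    out = {
        "superres_fwhm_nm": sr,
        "diffraction_fwhm_nm": dl,
        "canvas_pitch_nm": canvas.pitch_nm,
        "canvas_pitch_display": canvas.pitch_display,
    }
    with open(OUT / "fwhm.json", "w") as fh:
        json.dump(out, fh, indent=1)
    print(f"super-res transverse FWHM (truth 116.5): {sr:.1f} nm")
    print(f"diffraction-limited FWHM (target 357): {dl:.1f} nm")
    print(f"canvas pitch: {canvas.pitch_nm} nm ({canvas.pitch_display})")


if __name__ == "__main__":
    main()
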