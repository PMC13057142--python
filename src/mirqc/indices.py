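"""Spectral summary indices.

The humification index is the ratio of two band intensities read from a
preprocessed (baseline-corrected, normalised) spectrum.  The default bands
are 1630 cm^-1 (aromatic C=C / carboxylate stretch, enriched in decomposed
organic matter) over 1090 cm^-1 (polysaccharide C-O stretch, depleted during
decomposition), so larger values indicate stronger humification.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import DomainError
from .spectrum import Spectrum, intensity_at


@dataclass
class IndexResult:
    name: str
    value: float
    x1: float
    x2: float


def humification_index(s: Spectrum, x1: float = 1630.0, x2: float = 1090.0) -> IndexResult:
    """Intensity ratio I(x1) / I(x2) at the nearest grid points."""
    i1 = intensity_at(s, x1)
    i2 = intensity_at(s, x2)
    if i2 == 0:
        raise DomainError(f"intensity at {x2} cm^-1 is 0; ratio undefined")
    return IndexResult(
        name=f"hi_{int(x1)}_{int(x2)}", value=i1 / i2, x1=float(x1), x2=float(x2)
    )
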