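"""Edge-level distances of the reference graph.

Two genes are near each other either because they are strong sequence
homologs (the homology-based distance, a clipped log-transform of the BLAST
E-value) or because they are neighbours predicted to share an operon (the
operon-based distance, the complement of the operon probability). Both map
their evidence onto [0, 1], with 0 meaning maximal confidence.
"""

from __future__ import annotations

import math

from .model import ValidationError

#: Exponent floor of BLAST E-values: values below 1e-185 are reported as 0,
#: so 185 normalizes the log-E-value onto [0, 1].
EVALUE_NORM = 185.0


def homology_distance(evalue: float, norm: float = EVALUE_NORM) -> float:
    """Distance in [0, 1] from a BLAST E-value.

    d_s(E) = clamp(1 + log10(E) / norm, 0, 1), with d_s(0) = 0: an E-value of
    0 (reported when E < 1e-185) is maximal similarity, an E-value of 1 or
    worse is maximal distance. Monotone non-decreasing in the E-value.
    """
    if evalue < 0:
        raise ValidationError(f"negative E-value {evalue}")
    if norm <= 0:
        raise ValidationError(f"norm must be positive, got {norm}")
    if evalue == 0.0:
        return 0.0
    d = 1.0 + math.log10(evalue) / norm
    return min(1.0, max(0.0, d))


def operon_distance(prob: float) -> float:
    """Distance in [0, 1] from a same-operon probability: d_o(p) = 1 - p."""
    if not 0.0 <= prob <= 1.0:
        raise ValidationError(f"operon probability {prob} outside [0, 1]")
    return 1.0 - prob


def symmetrized_evalue(evalue_ab: float, evalue_ba: float) -> float:
    """E-value of an unordered pair: the minimum over the two directions."""
    return min(evalue_ab, evalue_ba)
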