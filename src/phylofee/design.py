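"""Experiment-design bookkeeping for consortium assays.

The combinatorics that motivate landscape-based prediction: a k-strain
library spans 2^k - 1 possible non-empty consortia, far beyond what can be
assayed, while the actual design measures a structured subset (backgrounds
under several inoculation schemes, plus monocultures and pairwise
co-cultures).
"""

from __future__ import annotations

from math import comb

__all__ = ["design_counts", "n_possible_compositions"]


def design_counts(n_backgrounds: int, n_schemes: int, n_strains: int) -> dict:
    """Assay bookkeeping for a background x inoculation-scheme design.

    Returns the number of background assays (backgrounds x schemes),
    monocultures, pairwise co-cultures n(n-1)/2, their total, and the
    2^n - 1 possible non-empty consortia of the strain library.
    """
    if min(n_backgrounds, n_schemes, n_strains) < 0:
        raise ValueError("counts must be non-negative")
    background_assays = n_backgrounds * n_schemes
    monocultures = n_strains
    pairwise = n_strains * (n_strains - 1) // 2
    return {
        "background_assays": background_assays,
        "monocultures": monocultures,
        "pairwise": pairwise,
        "total_assays": background_assays + monocultures + pairwise,
        "possible_consortia": 2**n_strains - 1,
    }


def n_possible_compositions(n_strains: int, sizes) -> int:
    """Number of distinct consortia of the given richness values: sum of C(n, s)."""
    return sum(comb(n_strains, s) for s in sizes)
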