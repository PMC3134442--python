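"""Kyte-Doolittle hydropathy profiles and hydrophobic-stretch detection.

A hydropathy profile is the sliding-window mean (default window 7) of
per-residue Kyte-Doolittle scores.  Hydrophobic stretches are maximal
runs of >= 5 consecutive profile values strictly greater than 1; these
approximate the signal-sequence / transmembrane determinants recognised
cotranslationally by SRP.

Profile coordinates are 1-based window-start positions ("profile
space"); :func:`stretch_residue_span` maps a stretch back to the
residues it covers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import FormatError, InsufficientDataError

#: Kyte & Doolittle hydropathy scale.
KYTE_DOOLITTLE = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
    "R": -4.5,
}


@dataclass(frozen=True)
class HydropathyProfile:
    """Window-averaged hydropathy values along one protein."""

    sequence_id: str
    window: int
    values: np.ndarray  # length L - window + 1

    @property
    def positions(self) -> np.ndarray:
        """1-based residue index of each window's first residue."""
        return np.arange(1, len(self.values) + 1)


@dataclass(frozen=True)
class HydrophobicStretch:
    """Maximal profile run above threshold; coordinates in profile space."""

    start: int  # 1-based, inclusive
    end: int  # 1-based, inclusive
    max_value: float

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _scores(sequence: str) -> np.ndarray:
    sequence = sequence.upper()
    out = np.empty(len(sequence))
    for i, aa in enumerate(sequence):
        try:
            out[i] = KYTE_DOOLITTLE[aa]
        except KeyError:
            if aa == "X":
                warnings.warn(
                    "residue 'X' scored as 0.0 in hydropathy profile",
                    stacklevel=3,
                )
                out[i] = 0.0
            else:
                raise FormatError(f"unknown residue {aa!r}") from None
    return out


def hydropathy_profile(
    sequence: str, window: int = 7, sequence_id: str = ""
) -> HydropathyProfile:
    """Sliding-window mean of Kyte-Doolittle scores.

    Parameters
    ----------
    sequence
        Amino-acid string over the 20 standard residues ('X' is scored 0
        with a warning).
    window
        Odd window width; value at position p averages residues
        p .. p+window-1.  No terminal padding: the profile has
        ``len(sequence) - window + 1`` values.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if len(sequence) < window:
        raise InsufficientDataError(
            f"sequence length {len(sequence)} < window {window}"
        )
    scores = _scores(sequence)
    kernel = np.ones(window) / window
    values = np.convolve(scores, kernel, mode="valid")
    return HydropathyProfile(sequence_id=sequence_id, window=window, values=values)


def mean_hydrophobicity(sequence: str, window: int = 7) -> float:
    """Whole-protein hydrophobicity: mean of the window-7 profile."""
    return float(hydropathy_profile(sequence, window=window).values.mean())


def nterm_hydrophobicity(
    sequence: str, n_residues: int = 50, window: int = 11
) -> float:
    """N-terminal hydrophobicity: mean window-11 profile over the first
    ``n_residues`` residues (whole sequence if shorter)."""
    prefix = sequence[: min(n_residues, len(sequence))]
    return float(hydropathy_profile(prefix, window=window).values.mean())


def find_stretches(
    profile: HydropathyProfile,
    threshold: float = 1.0,
    min_length: int = 5,
) -> list[HydrophobicStretch]:
    """Maximal runs of profile values strictly above ``threshold`` with
    run length >= ``min_length``, ordered by start position."""
    above = profile.values > threshold
    stretches: list[HydrophobicStretch] = []
    run_start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start >= min_length:
                stretches.append(
                    HydrophobicStretch(
                        start=run_start + 1,
                        end=i,
                        max_value=float(profile.values[run_start:i].max()),
                    )
                )
            run_start = None
    return stretches


def first_stretch_length(
    sequence: str,
    window: int = 7,
    threshold: float = 1.0,
    min_length: int = 5,
) -> int | None:
    """Length of the first (lowest-start) hydrophobic stretch, or None."""
    stretches = find_stretches(
        hydropathy_profile(sequence, window=window),
        threshold=threshold,
        min_length=min_length,
    )
    return stretches[0].length if stretches else None


def stretch_residue_span(
    stretch: HydrophobicStretch, window: int = 7
) -> tuple[int, int]:
    """Residue-space span [start, end + window - 1] covered by a stretch."""
    return stretch.start, stretch.end + window - 1


def max_hydrophobicity_in_region(
    sequence: str, start: int, end: int, window: int = 7
) -> float:
    """Maximum profile value among windows starting within the 1-based
    residue region [start, end]; an option for scoring annotated SS/TM
    regions by their peak rather than the whole-protein mean."""
    profile = hydropathy_profile(sequence, window=window)
    lo = max(start, 1)
    hi = min(end, len(profile.values))
    if hi < lo:
        raise InsufficientDataError("region contains no complete window")
    return float(profile.values[lo - 1 : hi].max())
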