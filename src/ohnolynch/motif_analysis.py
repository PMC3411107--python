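"""14-3-3-binding motif grammar and −2 serine enrichment.

A canonical (mode-1-like) 14-3-3-binding motif has at least one basic residue
at offsets −3 to −5 relative to the phosphorylated Ser/Thr, and never a
proline at +1. The window analysed here spans offsets −5..+2 around the
phosphoresidue (offset 0), padded with '-' at the protein termini.

The −2 position is of special interest: a phosphorylatable serine at −2 is
the commonest lynchpin-associated feature, and its frequency among binding
sites is compared against resampled background sets of phosphosites.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._util import truncated_percent
from .tabular_io import DataError, PhosphositeRecord, SequenceSet

#: window offsets relative to the phosphoresidue
WINDOW_OFFSETS = tuple(range(-5, 3))
#: index of the phosphoresidue within the 8-character window
CENTER_INDEX = 5
#: default basic-residue set for the −3..−5 requirement (H optional by flag)
DEFAULT_BASIC = frozenset("KR")


@dataclass(frozen=True)
class MotifWindow:
    """The 8-residue −5..+2 window around a phosphosite ('-' pads termini)."""

    protein_acc: str
    center_pos: int
    residues: str

    def __post_init__(self) -> None:
        if len(self.residues) != len(WINDOW_OFFSETS):
            raise DataError(f"window must have 8 residues, got {self.residues!r}")

    @property
    def center_residue(self) -> str:
        return self.residues[CENTER_INDEX]

    def at(self, offset: int) -> str:
        if offset not in WINDOW_OFFSETS:
            raise DataError(f"offset {offset} outside −5..+2")
        return self.residues[offset + CENTER_INDEX]


@dataclass(frozen=True)
class MotifFeatures:
    has_basic_m3_to_m5: bool
    plus1_proline: bool
    minus2_ST: bool

    @property
    def is_consensus(self) -> bool:
        return self.has_basic_m3_to_m5 and not self.plus1_proline


def extract_window(seq: str, pos: int, protein_acc: str = "") -> MotifWindow:
    """Extract the −5..+2 window around 1-based position ``pos`` of ``seq``."""
    if not (1 <= pos <= len(seq)):
        raise DataError(f"position {pos} out of range 1..{len(seq)}")
    chars = []
    for off in WINDOW_OFFSETS:
        idx = pos - 1 + off
        chars.append(seq[idx] if 0 <= idx < len(seq) else "-")
    return MotifWindow(protein_acc=protein_acc, center_pos=pos, residues="".join(chars))


def windows_from_sites(
    sites: Sequence[PhosphositeRecord], seqs: SequenceSet
) -> list[MotifWindow]:
    """Extract a window per site; sites whose protein has no sequence are an error."""
    out = []
    for s in sites:
        if s.protein_acc not in seqs:
            raise DataError(f"no sequence for {s.protein_acc!r}")
        out.append(extract_window(seqs[s.protein_acc], s.position, s.protein_acc))
    return out


def motif_features(
    w: MotifWindow,
    basic_set: frozenset[str] = DEFAULT_BASIC,
    include_histidine: bool = False,
) -> MotifFeatures:
    """Evaluate the motif grammar flags on a window ('-' matches nothing)."""
    basic = set(basic_set) | ({"H"} if include_histidine else set())
    return MotifFeatures(
        has_basic_m3_to_m5=any(w.at(off) in basic for off in (-5, -4, -3)),
        plus1_proline=w.at(1) == "P",
        minus2_ST=w.at(-2) in ("S", "T"),
    )


@dataclass(frozen=True)
class Minus2Fraction:
    n_sites: int
    n_minus2: int        # serines at −2 (the default definition)
    n_minus2_T: int      # threonines at −2, reported but not counted by default

    @property
    def fraction(self) -> float:
        return self.n_minus2 / self.n_sites

    @property
    def truncated_percent(self) -> int:
        return truncated_percent(self.n_minus2, self.n_sites)


def minus2_fraction(
    sites: Sequence[MotifWindow], count_threonine: bool = False
) -> Minus2Fraction:
    """Fraction of windows with a phosphorylatable serine at offset −2.

    Threonine at −2 is counted separately and only folded in when
    ``count_threonine`` is set (the default counts serines only).
    """
    if not sites:
        raise DataError("minus2_fraction needs at least one window")
    n_s = sum(1 for w in sites if w.at(-2) == "S")
    n_t = sum(1 for w in sites if w.at(-2) == "T")
    n_hit = n_s + n_t if count_threonine else n_s
    return Minus2Fraction(n_sites=len(sites), n_minus2=n_hit, n_minus2_T=n_t)


@dataclass(frozen=True)
class Minus2Result:
    """Observed −2-serine fraction against a resampled phosphosite background."""

    n_sites: int
    n_minus2: int
    fraction: float
    truncated_percent: int
    background_fractions: tuple[float, ...]
    empirical_p: float
    n_resamples: int
    seed: int


def background_minus2(
    observed: Sequence[MotifWindow],
    pool: Sequence[MotifWindow],
    n_draw: int | None = None,
    n_resamples: int = 999,
    seed: int = 0,
    count_threonine: bool = False,
) -> Minus2Result:
    """Compare the observed −2-S fraction with resampled background draws.

    Each resample draws ``n_draw`` windows (default: the observed set size)
    without replacement from the background pool. The empirical p-value uses
    the add-one permutation-test convention,
    ``(1 + #{background ≥ observed}) / (n_resamples + 1)``, so it is never 0.
    """
    obs = minus2_fraction(observed, count_threonine=count_threonine)
    if n_draw is None:
        n_draw = len(observed)
    if not (1 <= n_draw <= len(pool)):
        raise DataError(f"n_draw={n_draw} must be in 1..|pool|={len(pool)}")
    rng = np.random.default_rng(seed)
    hits = np.array(
        [1 if (w.at(-2) == "S" or (count_threonine and w.at(-2) == "T")) else 0
         for w in pool],
        dtype=np.int64,
    )
    fractions = []
    for _ in range(n_resamples):
        idx = rng.choice(len(pool), size=n_draw, replace=False)
        fractions.append(float(hits[idx].sum()) / n_draw)
    n_ge = sum(1 for f in fractions if f >= obs.fraction)
    return Minus2Result(
        n_sites=obs.n_sites,
        n_minus2=obs.n_minus2,
        fraction=obs.fraction,
        truncated_percent=obs.truncated_percent,
        background_fractions=tuple(fractions),
        empirical_p=(1 + n_ge) / (n_resamples + 1),
        n_resamples=n_resamples,
        seed=seed,
    )


def write_features(
    windows: Iterable[MotifWindow],
    path,
    basic_set: frozenset[str] = DEFAULT_BASIC,
    include_histidine: bool = False,
) -> None:
    rows = []
    for w in windows:
        f = motif_features(w, basic_set=basic_set, include_histidine=include_histidine)
        rows.append(
            (
                w.protein_acc,
                w.center_pos,
                w.residues,
                w.center_residue,
                f.has_basic_m3_to_m5,
                f.plus1_proline,
                f.minus2_ST,
                f.is_consensus,
            )
        )
    pd.DataFrame(
        rows,
        columns=[
            "protein_acc",
            "position",
            "window",
            "center_residue",
            "has_basic_m3_to_m5",
            "plus1_proline",
            "minus2_ST",
            "is_consensus",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_minus2_summary(result: Minus2Result, path) -> None:
    pd.DataFrame(
        [
            (
                result.n_sites,
                result.n_minus2,
                result.fraction,
                result.truncated_percent,
                result.empirical_p,
                result.n_resamples,
                result.seed,
            )
        ],
        columns=[
            "n_sites",
            "n_minus2",
            "fraction",
            "truncated_percent",
            "empirical_p",
            "n_resamples",
            "seed",
        ],
    ).to_csv(path, sep="\t", index=False)
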