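"""Barcode compliance QC, pairwise distances and divergence summaries.

Two distances are provided for aligned, equal-length COI-5P barcodes:

* uncorrected *p*-distance — the fraction of comparable sites that differ;
* Kimura two-parameter (K2P) distance,

  .. math:: d = -\\tfrac{1}{2}\\,\\ln\\bigl((1 - 2P - Q)\\sqrt{1 - 2Q}\\bigr)

  where *P* and *Q* are the transition and transversion fractions over
  comparable sites.  Transitions are A<->G and C<->T; every other change
  among A/C/G/T is a transversion.

Sites where either sequence carries a gap or an ambiguity code are excluded
pairwise ("pairwise deletion").  Sequences must be the same length: COI-5P
barcodes are effectively indel-free within an insect order, so pre-aligned
equal-length input is required rather than silently re-aligned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .bold_io import SpecimenRecord

logger = logging.getLogger(__name__)

GAP = "-"

# Reason codes for compliance failures.
TOO_SHORT = "TOO_SHORT"
TOO_AMBIGUOUS = "TOO_AMBIGUOUS"
NO_SEQUENCE = "NO_SEQUENCE"
NO_SPECIES = "NO_SPECIES"


class DistanceError(ValueError):
    """A pairwise distance could not be computed."""


class LengthMismatchError(DistanceError):
    pass


class NoComparableSitesError(DistanceError):
    pass


class SaturatedDistanceError(DistanceError):
    """The K2P logarithm's argument is non-positive: distance undefined."""


@dataclass(frozen=True)
class QCConfig:
    """Barcode data-standard thresholds.

    A compliant barcode is strictly longer than ``min_length`` (so 501 bp
    passes, 500 bp does not) and its ambiguity fraction is strictly below
    ``max_ambiguity_fraction`` (the "less than 1% Ns" rule).
    """

    min_length: int = 500
    max_ambiguity_fraction: float = 0.01
    require_species_name: bool = True

    def __post_init__(self) -> None:
        if self.min_length <= 0:
            raise ValueError("min_length must be positive")
        if not 0.0 < self.max_ambiguity_fraction < 1.0:
            raise ValueError("max_ambiguity_fraction must be in (0, 1)")


@dataclass(frozen=True)
class QCResult:
    passed: bool
    reasons: frozenset[str]


@dataclass(frozen=True)
class DistanceResult:
    """Pairwise distance with its site bookkeeping.

    ``k2p_dist`` is ``None`` unless computed via :func:`k2p_distance`.
    """

    comparable_sites: int
    transitions: int
    transversions: int
    P: float
    Q: float
    p_dist: float
    k2p_dist: float | None = None


@dataclass(frozen=True)
class DivergenceSummary:
    """Within-species pairwise divergence statistics.

    All statistics are undefined (``None``) when the species has fewer than
    two specimens and hence no pairs.  The standard error treats the pairwise
    distances as observations (SD / sqrt(n_pairs)); pairs sharing a specimen
    are not independent, so this SE understates uncertainty — it mirrors the
    simple summary style used in barcode-library reports.
    """

    species: str
    n_specimens: int
    n_pairs: int
    mean: float | None
    se: float | None
    min: float | None
    max: float | None


def sequence_length(seq: str) -> int:
    """Length over non-gap characters."""
    return sum(1 for c in seq if c != GAP)


def ambiguity_fraction(seq: str) -> float:
    """Fraction of non-gap characters that are not plain A/C/G/T."""
    n = amb = 0
    for c in seq:
        if c == GAP:
            continue
        n += 1
        if c not in "ACGT":
            amb += 1
    return amb / n if n else 0.0


def compliance_check(record: SpecimenRecord, cfg: QCConfig | None = None) -> QCResult:
    """Check one record against the barcode data standard.

    Total function: every applicable reason code is reported, never an
    exception.
    """
    cfg = cfg or QCConfig()
    reasons: set[str] = set()
    seq = record.sequence
    if not seq:
        reasons.add(NO_SEQUENCE)
    else:
        if sequence_length(seq) <= cfg.min_length:
            reasons.add(TOO_SHORT)
        if ambiguity_fraction(seq) >= cfg.max_ambiguity_fraction:
            reasons.add(TOO_AMBIGUOUS)
    if cfg.require_species_name and not record.species:
        reasons.add(NO_SPECIES)
    return QCResult(passed=not reasons, reasons=frozenset(reasons))


# ---------------------------------------------------------------------------
# Pairwise distances
# ---------------------------------------------------------------------------

# Encoding: A,C,G,T -> 0..3; every other character (ambiguity or gap) -> 255.
_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENCODE[ord(_b)] = _i
    _ENCODE[ord(_b.lower())] = _i

_PURINE = {0, 2}  # A, G


def encode_sequence(seq: str) -> np.ndarray:
    return _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _pair_counts(a: np.ndarray, b: np.ndarray) -> tuple[int, int, int]:
    """(comparable_sites, transitions, transversions) under pairwise deletion."""
    if a.shape != b.shape:
        raise LengthMismatchError(
            f"sequences differ in length ({a.size} vs {b.size}); "
            "distances require pre-aligned equal-length input"
        )
    ok = (a != 255) & (b != 255)
    n = int(ok.sum())
    if n == 0:
        raise NoComparableSitesError("no comparable sites between the two sequences")
    diff = ok & (a != b)
    # transition: both purines (A=0, G=2) or both pyrimidines (C=1, T=3);
    # under this encoding that is "same parity".
    ts = int((diff & ((a & 1) == (b & 1))).sum())
    tv = int(diff.sum()) - ts
    return n, ts, tv


def _as_codes(seq: str | np.ndarray) -> np.ndarray:
    return seq if isinstance(seq, np.ndarray) else encode_sequence(seq)


def p_distance(a: str | np.ndarray, b: str | np.ndarray) -> DistanceResult:
    """Uncorrected pairwise distance with pairwise deletion."""
    n, ts, tv = _pair_counts(_as_codes(a), _as_codes(b))
    return DistanceResult(
        comparable_sites=n,
        transitions=ts,
        transversions=tv,
        P=ts / n,
        Q=tv / n,
        p_dist=(ts + tv) / n,
    )


def k2p_from_fractions(P: float, Q: float) -> float:
    """K2P closed form d = -1/2 ln((1-2P-Q) sqrt(1-2Q))."""
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturatedDistanceError(
            f"K2P undefined for P={P:.4f}, Q={Q:.4f} (log argument non-positive)"
        )
    return -0.5 * math.log(w1 * math.sqrt(w2))


def k2p_distance(a: str | np.ndarray, b: str | np.ndarray) -> DistanceResult:
    """Kimura two-parameter distance; raises :class:`SaturatedDistanceError`
    when the correction is undefined rather than returning infinity."""
    res = p_distance(a, b)
    d = k2p_from_fractions(res.P, res.Q)
    # guard against -0.0 and tiny negative rounding at p=0
    d = max(d, 0.0)
    return DistanceResult(
        comparable_sites=res.comparable_sites,
        transitions=res.transitions,
        transversions=res.transversions,
        P=res.P,
        Q=res.Q,
        p_dist=res.p_dist,
        k2p_dist=d,
    )


_METRICS = {"p": p_distance, "k2p": k2p_distance}


def pair_distance(a: str | np.ndarray, b: str | np.ndarray, metric: str = "p") -> float:
    res = _METRICS[metric](a, b)
    return res.p_dist if metric == "p" else float(res.k2p_dist)


def distance_matrix(
    seqs: Mapping[str, str], metric: str = "p"
) -> tuple[list[str], np.ndarray]:
    """Symmetric pairwise distance matrix with a zero diagonal.

    Returns the IDs in input order and the matrix aligned to them.  Any
    pairwise failure is re-raised naming the offending pair.
    """
    if metric not in _METRICS:
        raise ValueError(f"unknown metric {metric!r}; expected 'p' or 'k2p'")
    ids = list(seqs)
    if not ids:
        raise ValueError("distance_matrix requires at least one sequence")
    codes = [encode_sequence(seqs[i]) for i in ids]
    n = len(ids)
    mat = np.zeros((n, n), dtype=float)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = pair_distance(codes[i], codes[j], metric)
            except DistanceError as exc:
                raise type(exc)(f"pair ({ids[i]}, {ids[j]}): {exc}") from exc
            mat[i, j] = mat[j, i] = d
    return ids, mat


def intraspecific_stats(
    species_to_seqs: Mapping[str, Mapping[str, str]], metric: str = "k2p"
) -> list[DivergenceSummary]:
    """Within-species divergence over all n(n-1)/2 pairs per species.

    Pairs whose distance is undefined (saturation, no comparable sites) are
    dropped with a warning; a species with no usable pair reports undefined
    statistics.
    """
    out: list[DivergenceSummary] = []
    for species, seqs in species_to_seqs.items():
        codes = [encode_sequence(s) for s in seqs.values()]
        dists: list[float] = []
        m = len(codes)
        for i in range(m):
            for j in range(i + 1, m):
                try:
                    dists.append(pair_distance(codes[i], codes[j], metric))
                except DistanceError as exc:
                    logger.warning("%s: dropping undefined pair (%s)", species, exc)
        if dists:
            arr = np.asarray(dists)
            se = 0.0 if arr.size == 1 else float(arr.std(ddof=1) / math.sqrt(arr.size))
            out.append(
                DivergenceSummary(
                    species=species,
                    n_specimens=m,
                    n_pairs=arr.size,
                    mean=float(arr.mean()),
                    se=se,
                    min=float(arr.min()),
                    max=float(arr.max()),
                )
            )
        else:
            out.append(
                DivergenceSummary(
                    species=species, n_specimens=m, n_pairs=0,
                    mean=None, se=None, min=None, max=None,
                )
            )
    return out


def compliant_sequences(
    records: Iterable[SpecimenRecord], cfg: QCConfig | None = None
) -> dict[str, str]:
    """Sequences of records passing the *sequence-level* part of QC.

    Species names are not required here: unidentified specimens still get
    clustered (that is how unnamed bins arise), but sub-length or
    ambiguity-rich sequences never enter a distance matrix.
    """
    cfg = cfg or QCConfig()
    seq_cfg = QCConfig(
        min_length=cfg.min_length,
        max_ambiguity_fraction=cfg.max_ambiguity_fraction,
        require_species_name=False,
    )
    return {
        r.process_id: r.sequence
        for r in records
        if compliance_check(r, seq_cfg).passed
    }


def flag_high_divergence(
    summaries: Iterable[DivergenceSummary], threshold: float = 0.02
) -> list[DivergenceSummary]:
    """Species whose mean intraspecific divergence strictly exceeds the
    threshold (default 2%) — candidates for cryptic species complexes.
    Sorted by mean, descending."""
    flagged = [s for s in summaries if s.mean is not None and s.mean > threshold]
    return sorted(flagged, key=lambda s: -s.mean)


def write_distance_matrix(
    ids: Sequence[str], mat: np.ndarray, path: str | Path
) -> None:
    pd.DataFrame(mat, index=list(ids), columns=list(ids)).to_csv(path, sep="\t")


def write_divergence_summaries(
    summaries: Iterable[DivergenceSummary], path: str | Path
) -> None:
    pd.DataFrame(
        [
            {
                "species": s.species,
                "n": s.n_specimens,
                "n_pairs": s.n_pairs,
                "mean": s.mean,
                "se": s.se,
                "min": s.min,
                "max": s.max,
            }
            for s in summaries
        ]
    ).to_csv(path, index=False)
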