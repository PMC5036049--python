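"""Sequence-derived per-residue descriptors.

Covers PSSM ingestion (PSI-BLAST ASCII dialect, columns canonicalized to
alphabetical amino-acid order), per-column conservation scores from an MSA
(Shannon entropy, relative entropy and Jensen-Shannon divergence against a
background distribution), static physicochemical/compositional features,
trained catalytic propensity, and sliding-window assembly of per-residue
feature rows into flat vectors with zero-padding plus a terminal-indicator
bit per window position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._aa import (
    AA20,
    AA_INDEX,
    BACKGROUND,
    CHARGE,
    DEFAULT_CATALYTIC_PROPENSITY,
    HYDROPATHY,
    POLARITY,
)
from .structure_model import CatalyticAnnotation

__all__ = [
    "PSSM",
    "ConservationProfile",
    "PSSMParseError",
    "read_pssm",
    "conservation",
    "static_features",
    "catalytic_propensity",
    "background_frequencies",
    "window_features",
]


class PSSMParseError(ValueError):
    """Raised on a malformed PSSM file; message names the offending row."""


@dataclass
class PSSM:
    """L x 20 position-specific log-odds matrix, columns in AA20 order."""

    matrix: np.ndarray
    source: str = "file"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError("PSSM must be an L x 20 matrix")

    def __len__(self) -> int:
        return len(self.matrix)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=[f"pssm_{a}" for a in AA20])


@dataclass
class ConservationProfile:
    """Per-column conservation scores of a query-anchored MSA."""

    shannon: np.ndarray
    relative_entropy: np.ndarray
    jsd: np.ndarray
    high_gap: np.ndarray = field(default=None)  # >90%-gap columns flagged

    def __post_init__(self):
        if self.high_gap is None:
            self.high_gap = np.zeros(len(self.shannon), dtype=bool)

    def __len__(self) -> int:
        return len(self.shannon)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shannon": self.shannon,
                "rel_entropy": self.relative_entropy,
                "jsd": self.jsd,
            }
        )


def read_pssm(path: str | Path) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The header line of single-letter column labels fixes the column order
    (PSI-BLAST emits 40 columns: 20 log-odds then 20 weighted percentages;
    only the first 20 are kept) and the result is reordered to the
    alphabetical AA20 convention.
    """
    header_order: list[str] | None = None
    rows: list[list[float]] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            tokens = raw.split()
            if not tokens:
                continue
            if header_order is None:
                if len(tokens) >= 20 and all(t in AA20 for t in tokens[:20]):
                    header_order = tokens[:20]
                continue
            if not tokens[0].isdigit():
                continue  # trailing statistics block
            if len(tokens) < 2 or tokens[1] not in AA20:
                raise PSSMParseError(f"{path}: row at line {lineno} lacks a residue letter")
            values = tokens[2 : 2 + 20]
            if len(values) < 20:
                raise PSSMParseError(
                    f"{path}: row {tokens[0]} (line {lineno}) has {len(values)} scores, expected 20"
                )
            try:
                rows.append([float(v) for v in values])
            except ValueError as exc:
                raise PSSMParseError(f"{path}: row {tokens[0]} (line {lineno}): {exc}") from None
    if header_order is None or not rows:
        raise PSSMParseError(f"{path}: no PSSM header/data found")
    matrix = np.asarray(rows)
    order = [header_order.index(a) for a in AA20]
    return PSSM(matrix[:, order], source="file")


def _column_frequencies(column: Iterable[str]) -> tuple[np.ndarray, int, int]:
    counts = np.zeros(20)
    gaps = 0
    for ch in column:
        if ch in AA_INDEX:
            counts[AA_INDEX[ch]] += 1
        else:
            gaps += 1
    total = int(counts.sum())
    freq = counts / total if total else counts
    return freq, total, gaps


def _kl(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / q[mask])))


def conservation(
    msa: Sequence[str], background: np.ndarray | None = None
) -> ConservationProfile:
    """Shannon entropy, relative entropy and JSD per query column of an MSA.

    The first sequence is the query; columns where it carries a gap are
    dropped so the profile aligns with the ungapped query sequence.  Gap
    characters are excluded from the frequency counts, and columns with
    more than 90% gaps are flagged ``high_gap``.  JSD uses equal mixing
    weights (1/2) against the background, so it is bounded by 1 bit.
    """
    if not msa:
        raise ValueError("empty MSA")
    length = len(msa[0])
    if any(len(s) != length for s in msa):
        raise ValueError("aligned sequences must have equal length")
    bg = BACKGROUND if background is None else np.asarray(background, dtype=float)
    bg = bg / bg.sum()
    query = msa[0]
    shannon, rel_entropy, jsd, high_gap = [], [], [], []
    for col in range(length):
        if query[col] not in AA_INDEX:
            continue
        freq, total, gaps = _column_frequencies(s[col] for s in msa)
        mix = 0.5 * (freq + bg)
        nz = freq > 0
        shannon.append(float(-np.sum(freq[nz] * np.log2(freq[nz]))))
        rel_entropy.append(_kl(freq, bg))
        jsd.append(0.5 * _kl(freq, mix) + 0.5 * _kl(bg, mix))
        high_gap.append(gaps > 0.9 * (total + gaps))
    return ConservationProfile(
        shannon=np.array(shannon),
        relative_entropy=np.array(rel_entropy),
        jsd=np.array(jsd),
        high_gap=np.array(high_gap, dtype=bool),
    )


def background_frequencies(sequences: Iterable[str]) -> np.ndarray:
    """Amino-acid frequencies over a sequence corpus (uniform fallback)."""
    counts = np.zeros(20)
    for seq in sequences:
        for ch in seq:
            if ch in AA_INDEX:
                counts[AA_INDEX[ch]] += 1
    if counts.sum() == 0:
        return np.full(20, 1 / 20)
    return counts / counts.sum()


def catalytic_propensity(
    records: Iterable[tuple[str, CatalyticAnnotation]], pseudocount: float = 1.0
) -> dict[str, float]:
    """Per-type log2 ratio of catalytic vs overall residue frequency.

    ``records`` pairs each sequence with its catalytic annotation; additive
    smoothing keeps unseen types finite.
    """
    cat = np.full(20, pseudocount)
    all_counts = np.full(20, pseudocount)
    for seq, ann in records:
        for i, ch in enumerate(seq):
            if ch not in AA_INDEX:
                continue
            all_counts[AA_INDEX[ch]] += 1
            if i in ann.catalytic_indices:
                cat[AA_INDEX[ch]] += 1
    ratio = (cat / cat.sum()) / (all_counts / all_counts.sum())
    return {a: float(np.log2(ratio[i])) for i, a in enumerate(AA20)}


def static_features(
    sequence: str,
    propensity: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Sequence-only per-residue features.

    Columns: residue-type one-hot (``is_*``, binary), hydropathy, charge,
    polarity, catalytic propensity (trained table or the shipped default),
    relative sequential position i/(L-1), chain length, and the global
    amino-acid composition (``aac_*``, identical in every row).
    """
    length = len(sequence)
    bad = sorted({ch for ch in sequence if ch not in AA_INDEX})
    if bad:
        raise ValueError(f"non-standard residue letters {bad}")
    prop = DEFAULT_CATALYTIC_PROPENSITY if propensity is None else propensity
    idx = np.array([AA_INDEX[ch] for ch in sequence])
    one_hot = np.zeros((length, 20))
    one_hot[np.arange(length), idx] = 1.0
    composition = one_hot.sum(axis=0) / length
    table = {f"is_{a}": one_hot[:, k] for k, a in enumerate(AA20)}
    table["hydropathy"] = HYDROPATHY[idx]
    table["charge"] = CHARGE[idx]
    table["polarity"] = POLARITY[idx]
    table["cat_propensity"] = np.array([prop[ch] for ch in sequence])
    table["seq_pos"] = np.arange(length) / (length - 1) if length > 1 else np.zeros(length)
    table["length"] = np.full(length, float(length))
    for k, a in enumerate(AA20):
        table[f"aac_{a}"] = np.full(length, composition[k])
    return pd.DataFrame(table, index=pd.RangeIndex(length, name="residue"))


def window_features(per_residue: pd.DataFrame | np.ndarray, center: int, half_width: int) -> np.ndarray:
    """Flatten rows ``center-w .. center+w`` into one vector.

    Out-of-chain positions contribute a zero block; every position gets a
    terminal-indicator bit (1 marks a padded, out-of-chain slot), so the
    vector length is ``(2w+1) * (n_features + 1)``.
    """
    values = per_residue.to_numpy() if isinstance(per_residue, pd.DataFrame) else np.asarray(per_residue)
    length, n_features = values.shape
    if not 0 <= center < length:
        raise IndexError(f"center {center} outside 0..{length - 1}")
    blocks = []
    for pos in range(center - half_width, center + half_width + 1):
        if 0 <= pos < length:
            blocks.append(np.append(values[pos], 0.0))
        else:
            blocks.append(np.append(np.zeros(n_features), 1.0))
    return np.concatenate(blocks)
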