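"""Jukes-Cantor nucleotide divergence: pairwise and between-group
distances, fixed-region matrices and sliding-window profiles.

The statistic throughout is the Jukes-Cantor corrected divergence
``d = -(3/4) ln(1 - (4/3) p)`` computed over all compared sites
(silent and replacement alike). Sites are compared under pairwise
deletion: per sequence pair, alignment columns where either residue is
a gap or an ambiguity code are excluded; complete deletion is available
as an option. The between-group statistic is the arithmetic mean of
corrected pairwise distances over all inter-group pairs (Dxy-style).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


class DivergenceError(ValueError):
    """Raised on invalid divergence input (e.g. no comparable sites)."""


@dataclass
class DistanceResult:
    """Observed mismatch proportion ``p``, corrected divergence ``d``
    (substitutions/site) and the number of compared sites."""

    p: float
    d: float
    sites: int


@dataclass
class WindowProfile:
    """Per-window between-group divergences along an alignment.

    ``starts`` are 1-based window start positions spaced ``step`` apart;
    ``values`` maps each comparison label to per-window mean d, with
    ``minima``/``maxima`` giving the per-window range over inter-group
    pairs (per-population spreads are reported alongside the mean).
    """

    window: int
    step: int
    starts: np.ndarray
    values: dict[str, np.ndarray]
    minima: dict[str, np.ndarray]
    maxima: dict[str, np.ndarray]

    @property
    def midpoints(self) -> np.ndarray:
        return self.starts + (self.window - 1) / 2.0

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {
            "start": self.starts,
            "midpoint": self.midpoints,
        }
        for label, vals in self.values.items():
            cols[label] = vals
            cols[f"{label}:min"] = self.minima[label]
            cols[f"{label}:max"] = self.maxima[label]
        return pd.DataFrame(cols)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.6f")


@dataclass
class DistanceMatrix:
    """Symmetric matrix of divergences between samples over a region.

    ``unit`` records whether values are ``percent`` (100*d) or
    ``per-site``.
    """

    labels: list[str]
    values: np.ndarray
    region: str
    unit: str = "percent"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise DivergenceError("matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T):
            raise DivergenceError("matrix is not symmetric")
        if np.any(np.diag(self.values) != 0):
            raise DivergenceError("matrix diagonal must be zero")

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])


_ACGT = frozenset(b"ACGT")


def _byte_arrays(a: str, b: str) -> tuple[np.ndarray, np.ndarray]:
    if len(a) != len(b):
        raise DivergenceError("sequences must be aligned to equal length")
    return (
        np.frombuffer(a.encode(), dtype=np.uint8),
        np.frombuffer(b.encode(), dtype=np.uint8),
    )


def _valid_mask(arr: np.ndarray) -> np.ndarray:
    return (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))


def pairwise_p(a: str, b: str) -> DistanceResult:
    """Observed mismatch proportion between two aligned sequences under
    pairwise deletion; ``d`` is left NaN here (see :func:`jc_correct`).
    """
    aa, bb = _byte_arrays(a, b)
    both = _valid_mask(aa) & _valid_mask(bb)
    sites = int(both.sum())
    if sites == 0:
        raise DivergenceError("no comparable sites")
    p = float(((aa != bb) & both).sum()) / sites
    return DistanceResult(p=p, d=math.nan, sites=sites)


def jc_correct(p: float) -> float:
    """Jukes-Cantor correction ``d = -(3/4) ln(1 - (4/3) p)``; defined
    for 0 <= p < 0.75."""
    if not 0.0 <= p < 0.75:
        raise DivergenceError(f"p={p} outside the Jukes-Cantor domain [0, 0.75)")
    return -0.75 * math.log1p(-(4.0 / 3.0) * p)


def pairwise_jc(a: str, b: str) -> DistanceResult:
    """Jukes-Cantor corrected distance between two aligned sequences."""
    res = pairwise_p(a, b)
    res.d = jc_correct(res.p)
    return res


def _resolve(alignment, ids) -> list[str]:
    if isinstance(alignment, dict):
        missing = [i for i in ids if i not in alignment]
        if missing:
            raise DivergenceError(f"unknown sample ids {missing}")
        return [alignment[i] for i in ids]
    by_id = {rec.id: rec.residues for rec in alignment}
    missing = [i for i in ids if i not in by_id]
    if missing:
        raise DivergenceError(f"unknown sample ids {missing}")
    return [by_id[i] for i in ids]


def _slice(seq: str, region: tuple[int, int] | None) -> str:
    if region is None:
        return seq
    start, end = region
    if not (1 <= start <= end <= len(seq)):
        raise DivergenceError(
            f"region {start}-{end} invalid for alignment of length {len(seq)}"
        )
    return seq[start - 1 : end]


def group_divergence(
    alignment,
    group_a_ids: list[str],
    group_b_ids: list[str],
    region: tuple[int, int] | None = None,
) -> DistanceResult:
    """Between-group mean Jukes-Cantor divergence (Dxy-style): the
    arithmetic mean of corrected distances over all inter-group pairs,
    optionally restricted to a 1-based inclusive region."""
    if not group_a_ids or not group_b_ids:
        raise DivergenceError("groups must be non-empty")
    if set(group_a_ids) & set(group_b_ids):
        raise DivergenceError("groups must be disjoint")
    seqs_a = [_slice(s, region) for s in _resolve(alignment, group_a_ids)]
    seqs_b = [_slice(s, region) for s in _resolve(alignment, group_b_ids)]
    ds, ps, sites = [], [], []
    for sa in seqs_a:
        for sb in seqs_b:
            res = pairwise_jc(sa, sb)
            ds.append(res.d)
            ps.append(res.p)
            sites.append(res.sites)
    return DistanceResult(
        p=float(np.mean(ps)), d=float(np.mean(ds)), sites=int(np.mean(sites))
    )


def _pair_window_d(sa: str, sb: str, starts: np.ndarray, window: int) -> np.ndarray:
    """Per-window JC distance for one pair via cumulative-sum scans."""
    aa, bb = _byte_arrays(sa, sb)
    both = (_valid_mask(aa) & _valid_mask(bb)).astype(np.int64)
    diff = ((aa != bb) & (both == 1)).astype(np.int64)
    csites = np.concatenate([[0], np.cumsum(both)])
    cdiff = np.concatenate([[0], np.cumsum(diff)])
    lo = starts - 1
    hi = lo + window
    sites = csites[hi] - csites[lo]
    mism = cdiff[hi] - cdiff[lo]
    out = np.empty(len(starts))
    for k in range(len(starts)):
        if sites[k] == 0:
            raise DivergenceError(
                f"no comparable sites in window starting at {starts[k]}"
            )
        out[k] = jc_correct(mism[k] / sites[k])
    return out


def sliding_window(
    alignment,
    comparisons: list[tuple[str, list[str], list[str]]],
    window: int = 657,
    step: int = 5,
) -> WindowProfile:
    """Sliding-window between-group divergence profile.

    Windows start at 1, 1+step, ... while ``start + window - 1`` fits in
    the alignment; the final partial window is discarded. Each window's
    value is the between-group mean JC divergence restricted to the
    window, with min/max over inter-group pairs recorded alongside.
    """
    if step < 1:
        raise DivergenceError("step must be >= 1")
    seqs = (
        list(alignment.values())
        if isinstance(alignment, dict)
        else [r.residues for r in alignment]
    )
    length = len(seqs[0])
    if window > length:
        raise DivergenceError(
            f"window {window} exceeds alignment length {length}"
        )
    nwin = (length - window) // step + 1
    starts = 1 + step * np.arange(nwin)
    values: dict[str, np.ndarray] = {}
    minima: dict[str, np.ndarray] = {}
    maxima: dict[str, np.ndarray] = {}
    for label, ids_a, ids_b in comparisons:
        if set(ids_a) & set(ids_b):
            raise DivergenceError(f"comparison {label!r}: groups overlap")
        seqs_a = _resolve(alignment, ids_a)
        seqs_b = _resolve(alignment, ids_b)
        per_pair = np.stack(
            [_pair_window_d(sa, sb, starts, window) for sa in seqs_a for sb in seqs_b]
        )
        values[label] = per_pair.mean(axis=0)
        minima[label] = per_pair.min(axis=0)
        maxima[label] = per_pair.max(axis=0)
    return WindowProfile(
        window=window, step=step, starts=starts,
        values=values, minima=minima, maxima=maxima,
    )


def region_matrix(
    alignment,
    samples: list[str],
    region: tuple[int, int] | None = None,
    region_name: str | None = None,
) -> DistanceMatrix:
    """Symmetric matrix of percent JC divergence (100*d) between all
    sample pairs over a region (``None`` = the whole alignment /
    concatenation)."""
    seqs = dict(zip(samples, (_slice(s, region) for s in _resolve(alignment, samples))))
    n = len(samples)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_jc(seqs[samples[i]], seqs[samples[j]]).d
            vals[i, j] = vals[j, i] = 100.0 * d
    name = region_name or (
        f"{region[0]}-{region[1]}" if region is not None else "concatenation"
    )
    return DistanceMatrix(labels=list(samples), values=vals, region=name)


def export_matrix(matrix: DistanceMatrix, path: str | Path, fmt: str = "tsv") -> None:
    """Write a matrix as square PHYLIP (per-site values) or TSV
    (percent values); the unit is stated in a header comment."""
    for label in matrix.labels:
        if not label:
            raise DivergenceError("empty sample label")
    if fmt == "phylip":
        with open(path, "w") as fh:
            fh.write(f"{len(matrix.labels)}\n")
            scale = 0.01 if matrix.unit == "percent" else 1.0
            for label, row in zip(matrix.labels, matrix.values):
                name = label[:10].ljust(10)
                fh.write(name + "  " + "  ".join(f"{v * scale:.6f}" for v in row) + "\n")
    elif fmt == "tsv":
        with open(path, "w") as fh:
            fh.write(f"# region={matrix.region} unit={matrix.unit}\n")
            fh.write("sample\t" + "\t".join(matrix.labels) + "\n")
            for label, row in zip(matrix.labels, matrix.values):
                fh.write(label + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")
    else:
        raise DivergenceError(f"unknown matrix format {fmt!r}")


def import_matrix_tsv(path: str | Path) -> DistanceMatrix:
    """Read back a TSV matrix written by :func:`export_matrix`."""
    with open(path) as fh:
        header = fh.readline().strip()
        df = pd.read_csv(fh, sep="\t", index_col=0)
    meta = dict(tok.split("=", 1) for tok in header.lstrip("# ").split())
    return DistanceMatrix(
        labels=list(df.index),
        values=df.to_numpy(),
        region=meta.get("region", "?"),
        unit=meta.get("unit", "percent"),
    )


def plot_profile(
    profile: WindowProfile,
    path: str | Path,
    threshold: float = 3.5,
) -> None:
    """Plot percent divergence against window midpoint with a horizontal
    species-boundary rule (default 3.5%)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    for label, vals in profile.values.items():
        ax.plot(profile.midpoints, 100.0 * vals, label=label)
    ax.axhline(threshold, color="grey", lw=1)
    ax.set_xlabel("window midpoint (bp)")
    ax.set_ylabel("divergence (K-JC, %)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
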