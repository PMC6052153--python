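"""Threshold-based putative-species delimitation and cross-region
concordance analysis.

Samples are grouped by single-linkage at a percent-divergence threshold
(default 3.5): two samples share a cluster iff they are connected by a
chain of pairwise divergences strictly below the threshold; a pair at
or above the threshold splits. Complete linkage is available for
sensitivity analysis. Running the delimitation over several gene
regions exposes discordant pairs — pairs whose co-cluster status flips
between regions, the signature of region-dependent barcode divergence.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .divergence import DistanceMatrix, DivergenceError, pairwise_p


class DelimitationError(ValueError):
    """Raised on invalid delimitation input."""


@dataclass
class DiscordantPair:
    sample_a: str
    sample_b: str
    joined_in: list[str]
    split_in: list[str]
    values: dict[str, float]  # region -> percent divergence


@dataclass
class DelimitationResult:
    """Clusters per region plus the discordance list."""

    threshold: float
    clusters_by_region: dict[str, list[list[str]]]
    discordant_pairs: list[DiscordantPair] = field(default_factory=list)

    def to_json(self, path=None) -> str:
        payload = {
            "threshold": self.threshold,
            "clusters": self.clusters_by_region,
            "discordant_pairs": [
                {
                    "pair": [p.sample_a, p.sample_b],
                    "joined_in": p.joined_in,
                    "split_in": p.split_in,
                    "values": p.values,
                }
                for p in self.discordant_pairs
            ],
        }
        text = json.dumps(payload, indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def to_text(self) -> str:
        lines = [f"threshold: {self.threshold}%  (pairs at or above it split)"]
        for region, clusters in self.clusters_by_region.items():
            parts = "; ".join("{" + ", ".join(c) + "}" for c in clusters)
            lines.append(f"{region}: {parts}")
        if self.discordant_pairs:
            lines.append("discordant pairs:")
            for p in self.discordant_pairs:
                vals = ", ".join(f"{r}={v:.2f}%" for r, v in p.values.items())
                lines.append(
                    f"  {p.sample_a} / {p.sample_b}: joined in "
                    f"{','.join(p.joined_in)}; split in {','.join(p.split_in)} ({vals})"
                )
        else:
            lines.append("no discordant pairs")
        return "\n".join(lines)


def single_linkage_delimit(
    matrix: DistanceMatrix, threshold: float = 3.5, linkage: str = "single"
) -> list[list[str]]:
    """Partition samples at the divergence threshold (percent).

    ``single`` linkage joins samples connected by a chain of pairwise
    divergences strictly below the threshold (a pair at exactly the
    threshold is split). ``complete`` linkage requires every pair inside
    a cluster to be below the threshold.
    """
    labels = matrix.labels
    n = len(labels)
    vals = matrix.values
    if matrix.unit != "percent":
        vals = 100.0 * vals
    if linkage == "single":
        adj = (vals < threshold).astype(np.int8)
        np.fill_diagonal(adj, 0)
        _, comp = connected_components(csr_matrix(adj), directed=False)
    elif linkage == "complete":
        from scipy.cluster.hierarchy import fcluster, linkage as _hlink
        from scipy.spatial.distance import squareform

        if n == 1:
            comp = np.zeros(1, dtype=int)
        else:
            Z = _hlink(squareform(vals, checks=False), method="complete")
            comp = fcluster(Z, t=np.nextafter(threshold, -np.inf), criterion="distance")
    else:
        raise DelimitationError(f"unknown linkage {linkage!r}")
    clusters: dict[int, list[str]] = {}
    for lab, c in zip(labels, comp):
        clusters.setdefault(int(c), []).append(lab)
    # deterministic order: by first member's position in the label list
    ordered = sorted(clusters.values(), key=lambda c: labels.index(c[0]))
    return [sorted(c, key=labels.index) for c in ordered]


def discordance_report(
    matrices_by_region: dict[str, DistanceMatrix],
    threshold: float = 3.5,
    linkage: str = "single",
) -> DelimitationResult:
    """Delimit every region and list pairs whose co-cluster status flips
    between regions, with the pairwise divergences in each region."""
    if len(matrices_by_region) < 2:
        raise DelimitationError("need at least two region matrices")
    label_sets = {tuple(sorted(m.labels)) for m in matrices_by_region.values()}
    if len(label_sets) > 1:
        raise DelimitationError("matrices have mismatching sample labels")
    clusters_by_region = {
        region: single_linkage_delimit(m, threshold, linkage)
        for region, m in matrices_by_region.items()
    }
    membership: dict[str, dict[str, int]] = {}
    for region, clusters in clusters_by_region.items():
        membership[region] = {
            lab: ci for ci, cluster in enumerate(clusters) for lab in cluster
        }
    labels = next(iter(matrices_by_region.values())).labels
    pairs: list[DiscordantPair] = []
    for a, b in combinations(labels, 2):
        joined = [
            r for r in matrices_by_region if membership[r][a] == membership[r][b]
        ]
        split = [
            r for r in matrices_by_region if membership[r][a] != membership[r][b]
        ]
        if joined and split:
            pairs.append(
                DiscordantPair(
                    sample_a=a,
                    sample_b=b,
                    joined_in=joined,
                    split_in=split,
                    values={
                        r: m.get(a, b) for r, m in matrices_by_region.items()
                    },
                )
            )
    return DelimitationResult(
        threshold=threshold,
        clusters_by_region=clusters_by_region,
        discordant_pairs=pairs,
    )


def similarity_report(
    partials: list, reference_partial, min_identity: float = 0.0
) -> dict[str, float | None]:
    """Percent identity, 100*(1-p) over compared sites, of each partial
    to a reference partial. Unalignable or incomparable records report
    None instead of aborting the run."""
    from .align import UnalignableError, map_partial_to_reference
    from .seqio import SequenceRecord

    ref = (
        reference_partial.residues
        if isinstance(reference_partial, SequenceRecord)
        else str(reference_partial)
    )
    out: dict[str, float | None] = {}
    for i, p in enumerate(partials):
        rec = p if isinstance(p, SequenceRecord) else None
        seq = rec.residues if rec else str(p)
        name = rec.id if rec else f"partial_{i + 1}"
        try:
            if len(seq) == len(ref):
                res = pairwise_p(seq, ref)
            else:
                mapped = map_partial_to_reference(seq, ref, min_identity=min_identity)
                res = pairwise_p(
                    mapped.alignment.aligned_a.replace("-", "N"),
                    mapped.alignment.aligned_b.replace("-", "N"),
                )
            out[name] = 100.0 * (1.0 - res.p)
        except (UnalignableError, DivergenceError):
            out[name] = None
    return out
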