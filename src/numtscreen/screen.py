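"""Four-criterion screening of partial mtCOI haplotypes for nuclear
mitochondrial pseudogenes (NUMTs) and erroneous sequences.

A partial barcode haplotype is flagged as a potential pseudogene if it
shows any of:

i.   interior INDELs relative to the group's full-length reference gene
     (a length change is incompatible with a functional protein-coding
     mitochondrial sequence);
ii.  premature stop codons under the invertebrate mitochondrial genetic
     code (only INDEL-free sequences can be read in frame);
iii. anomalous polymorphism: a terminal cluster of non-synonymous
     substitutions, an outlying whole-sequence divergence from the group
     consensus, or higher identity to a local decoy set (other species /
     chloroplast) than to the group consensus;
iv.  amino-acid substitutions at positions conserved across a reference
     panel of congeneric protein sequences (only sequences passing
     criteria i and ii are analysed at the amino-acid level).

Counts per criterion are raw (a haplotype may fail several), while the
"potential NUMTs" union counts each haplotype once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

from .align import (
    DEFAULT_SCORING,
    IndelEvent,
    MappedPartial,
    Scoring,
    UnalignableError,
    call_indels,
    map_partial_to_reference,
    progressive_align,
)
from .seqio import SequenceRecord


class ScreenError(ValueError):
    """Raised on invalid screening input."""


@dataclass(frozen=True)
class ScreenConfig:
    """Tunable thresholds of the pseudogene screen.

    The cluster and outlier cut-offs are deliberately configurable: they
    bracket observed pseudogene lesions (terminal non-synonymous
    stretches of roughly 9-116 bp; whole-sequence outliers near 5%)
    against normal within-group spreads (at or below ~1.4%).
    """

    cluster_min_len: int = 9      # bp; smallest terminal window considered
    cluster_max_len: int = 120    # bp; largest terminal window scanned
    cluster_density: float = 0.1  # non-synonymous substitutions per bp
    cluster_min_subs: int = 2     # minimum substitutions forming a cluster
    outlier_pct: float = 4.0      # % divergence from group consensus
    min_identity: float = 0.6     # mapping identity floor
    genetic_code: int = 5         # NCBI table: invertebrate mitochondrial
    min_aa_len: int = 30          # aa; shorter translations not assessed (iv)
    min_group_for_outlier: int = 3
    scoring: Scoring = DEFAULT_SCORING


DEFAULT_CONFIG = ScreenConfig()


@dataclass
class ReferencePanel:
    """Aligned amino-acid sequences from reference species, with a
    per-column flag marking positions conserved across all members."""

    rows: list[str]
    conserved_mask: np.ndarray

    @property
    def conserved_residues(self) -> str:
        return self.rows[0]

    def __len__(self) -> int:
        return len(self.rows[0])


@dataclass
class CriterionFlags:
    """Per-haplotype screening outcome with supporting evidence."""

    haplotype_id: str
    flag_i: bool = False
    flag_ii: bool = False
    flag_iii: bool = False
    flag_iv: bool = False
    analysed_at_aa_level: bool = False
    evidence: list[tuple[str, str, str]] = field(default_factory=list)

    @property
    def any_flag(self) -> bool:
        return self.flag_i or self.flag_ii or self.flag_iii or self.flag_iv


@dataclass
class GroupCounts:
    total: int
    count_i: int
    count_ii: int
    count_iii: int
    count_iv: int
    union: int

    @property
    def percent(self) -> float:
        return round(100.0 * self.union / self.total, 1) if self.total else 0.0


@dataclass
class ScreenReport:
    """Per-group summary of the four-criterion screen."""

    groups: dict[str, GroupCounts]
    unalignable: list[tuple[str, str]] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, g in self.groups.items():
            rows.append(
                {
                    "group": name,
                    "total_haplotypes": g.total,
                    "i_indel": g.count_i,
                    "ii_stop": g.count_ii,
                    "iii_polymorphisms": g.count_iii,
                    "iv_aa_change": g.count_iv,
                    "potential_numts_total": g.union,
                    "percent": g.percent,
                }
            )
        return pd.DataFrame(rows)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path=None) -> str:
        payload = {
            name: {
                "total": g.total,
                "i": g.count_i,
                "ii": g.count_ii,
                "iii": g.count_iii,
                "iv": g.count_iv,
                "union": g.union,
                "percent": g.percent,
            }
            for name, g in self.groups.items()
        }
        text = json.dumps(
            {"groups": payload, "unalignable": self.unalignable}, indent=2, sort_keys=True
        )
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def _residues(x) -> str:
    return x.residues if isinstance(x, SequenceRecord) else str(x)


def translate_mt(dna: str, code_id: int = 5) -> str:
    """Translate a frame-trimmed DNA string under the given NCBI genetic
    code (default: invertebrate mitochondrial, where TGA=Trp, ATA=Met)."""
    n = len(dna) - len(dna) % 3
    if n == 0:
        return ""
    return str(Seq(dna[:n]).translate(table=code_id))


def build_reference_panel(proteins: list[str]) -> ReferencePanel:
    """Build the conserved-site mask from >=2 reference protein
    sequences; unequal-length inputs are aligned progressively first.
    A column is conserved exactly when all rows share one residue and
    none has a gap."""
    rows = [_residues(p) for p in proteins]
    if len(rows) < 2:
        raise ScreenError("a reference panel needs at least 2 protein sequences")
    if len(set(map(len, rows))) > 1:
        rows = progressive_align(rows)
    arr = np.array([list(r) for r in rows])
    mask = np.array(
        [
            len(set(arr[:, j])) == 1 and arr[0, j] != "-"
            for j in range(arr.shape[1])
        ]
    )
    return ReferencePanel(rows=["".join(r) for r in arr], conserved_mask=mask)


_CODE_CACHE: dict[int, dict] = {}


def _code(code_id: int):
    if code_id not in _CODE_CACHE:
        table = CodonTable.unambiguous_dna_by_id[code_id]
        fwd = dict(table.forward_table)
        for stop in table.stop_codons:
            fwd[stop] = "*"
        _CODE_CACHE[code_id] = fwd
    return _CODE_CACHE[code_id]


def is_nonsynonymous(
    reference: str, ref_pos: int, obs_base: str, code_id: int = 5
) -> bool | None:
    """Whether substituting ``obs_base`` at 1-based ``ref_pos`` changes
    the amino acid of the reference codon (stop gain/loss counts as a
    change). Returns None when the site cannot be evaluated."""
    code = _code(code_id)
    ci = (ref_pos - 1) // 3
    cod = reference[3 * ci : 3 * ci + 3]
    if len(cod) < 3 or any(b not in "ACGT" for b in cod) or obs_base not in "ACGT":
        return None
    pos = (ref_pos - 1) % 3
    alt = cod[:pos] + obs_base + cod[pos + 1 :]
    return code[alt] != code[cod]


@dataclass
class _View:
    """A partial projected into reference coordinates."""

    record: SequenceRecord
    mapped: MappedPartial
    # (ref_pos, ref_base, obs_base, query_pos) for substitution columns
    mismatches: list[tuple[int, str, str, int]]
    proj: np.ndarray  # uint8 over 1..len(ref); 0 = not covered
    covered: tuple[int, int]  # first/last covered reference position

    @property
    def qlen(self) -> int:
        return len(self.record.residues)


def _make_view(record: SequenceRecord, reference: str, config: ScreenConfig) -> _View:
    mapped = map_partial_to_reference(
        record.residues, reference, config.scoring, config.min_identity
    )
    proj = np.zeros(len(reference) + 1, dtype=np.uint8)
    mism: list[tuple[int, str, str, int]] = []
    refpos = mapped.ref_offset - 1
    qpos = 0
    top, bot = mapped.alignment.aligned_a, mapped.alignment.aligned_b
    first = last = None
    for x, y in zip(top, bot):
        if y != "-":
            refpos += 1
        if x != "-":
            qpos += 1
        if x != "-" and y != "-":
            proj[refpos] = ord(x)
            if first is None:
                first = refpos
            last = refpos
            if x != y:
                mism.append((refpos, y, x, qpos))
    return _View(record, mapped, mism, proj, (first or 0, last or 0))


def screen_criterion_i(
    partial, reference, config: ScreenConfig = DEFAULT_CONFIG
) -> tuple[bool, list[IndelEvent]]:
    """Criterion i: interior INDELs relative to the reference."""
    mapped = map_partial_to_reference(
        _residues(partial), _residues(reference), config.scoring, config.min_identity
    )
    events = call_indels(mapped)
    return bool(events), events


def screen_criterion_ii(
    partial,
    frame_offset: int,
    config: ScreenConfig = DEFAULT_CONFIG,
    ref_offset: int | None = None,
    reference_length: int | None = None,
) -> tuple[bool, list[int]]:
    """Criterion ii: premature stop codons in frame-trimmed translation.

    ``frame_offset`` is the codon phase of the partial's first base (from
    mapping). When reference coordinates are supplied, stop positions are
    reported as 1-based reference codon starts and a stop occupying the
    gene's terminal codon is not premature.
    """
    seq = _residues(partial)
    lead = (3 - frame_offset) % 3
    aa = translate_mt(seq[lead:], config.genetic_code)
    stops: list[int] = []
    for k, res in enumerate(aa):
        if res != "*":
            continue
        if ref_offset is not None:
            codon_start = ref_offset + lead + 3 * k
            if reference_length is not None and codon_start == reference_length - 2:
                continue  # the gene's own terminal stop
            stops.append(codon_start)
        else:
            stops.append(lead + 3 * k + 1)
    return bool(stops), stops


def _cluster_hit(
    distances: list[int], config: ScreenConfig, qlen: int
) -> tuple[int, int] | None:
    """Given sorted distances (bp from one sequence end, 1-based) of
    non-synonymous substitutions, return (count, window) of a terminal
    cluster satisfying the density rule, or None."""
    for k, d in enumerate(distances, start=1):
        if k < config.cluster_min_subs:
            continue
        if d > min(config.cluster_max_len, qlen):
            break
        window = max(d, config.cluster_min_len)
        if k / window >= config.cluster_density:
            return k, window
    return None


def _consensus_from_views(views: list[_View], reference: str) -> np.ndarray:
    """Majority-rule consensus over reference coordinates; ties resolve
    to the reference base when it is among the leaders, else to the
    alphabetically first base. Uncovered positions are 0."""
    L = len(reference)
    counts = np.zeros((4, L + 1), dtype=np.int32)
    bases = b"ACGT"
    for v in views:
        for bi, base in enumerate(bases):
            counts[bi] += (v.proj == base).astype(np.int32)
    cons = np.zeros(L + 1, dtype=np.uint8)
    tot = counts.sum(axis=0)
    top = counts.max(axis=0)
    for pos in range(1, L + 1):
        if tot[pos] == 0:
            continue
        leaders = [bases[bi] for bi in range(4) if counts[bi, pos] == top[pos]]
        refb = ord(reference[pos - 1])
        cons[pos] = refb if refb in leaders else leaders[0]
    return cons


def _identity_vs_array(view: _View, other: np.ndarray) -> float | None:
    both = (view.proj > 0) & (other > 0)
    n = int(both.sum())
    if n == 0:
        return None
    return float((view.proj[both] == other[both]).sum()) / n


def _criterion_iii_view(
    view: _View,
    consensus: np.ndarray | None,
    group_size: int,
    reference: str,
    decoy_views: list[tuple[str, np.ndarray]],
    config: ScreenConfig,
) -> tuple[bool, list[tuple[str, str]]]:
    evidence: list[tuple[str, str]] = []
    flag = False

    # (a) terminal clusters of non-synonymous substitutions
    ns_q = [
        qpos
        for ref_pos, _rb, obs, qpos in view.mismatches
        if is_nonsynonymous(reference, ref_pos, obs, config.genetic_code)
    ]
    for end, distances in (
        ("5'", sorted(ns_q)),
        ("3'", sorted(view.qlen - q + 1 for q in ns_q)),
    ):
        hit = _cluster_hit(distances, config, view.qlen)
        if hit:
            flag = True
            evidence.append(
                (
                    "cluster",
                    f"{hit[0]} non-synonymous substitutions within {hit[1]} bp "
                    f"of the {end} end",
                )
            )

    # (b) outlying whole-sequence divergence from the group consensus
    if consensus is not None and group_size >= config.min_group_for_outlier:
        both = (view.proj > 0) & (consensus > 0)
        n = int(both.sum())
        if n:
            pct = 100.0 * float((view.proj[both] != consensus[both]).sum()) / n
            if pct >= config.outlier_pct:
                flag = True
                evidence.append(
                    ("outlier", f"{pct:.2f}% divergence from group consensus over {n} sites")
                )

    # (c) identity to a local decoy set exceeding identity to consensus
    if decoy_views:
        cons_id = _identity_vs_array(view, consensus) if consensus is not None else None
        if cons_id is not None:
            for name, dproj in decoy_views:
                did = _identity_vs_array(view, dproj)
                if did is not None and did > cons_id:
                    flag = True
                    evidence.append(
                        (
                            "decoy",
                            f"identity to decoy {name} ({100 * did:.2f}%) exceeds "
                            f"identity to group consensus ({100 * cons_id:.2f}%)",
                        )
                    )
    else:
        evidence.append(("decoy", "decoy set empty; identity check disabled"))
    return flag, evidence


def screen_criterion_iii(
    partial,
    group_haplotypes: list,
    reference,
    decoys: list | None = None,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> tuple[bool, list[tuple[str, str]]]:
    """Criterion iii: anomalous polymorphisms (terminal non-synonymous
    clusters; outlying divergence from the group consensus when the
    group has >= 3 haplotypes; higher identity to a decoy than to the
    consensus)."""
    ref = _residues(reference)
    rec = (
        partial
        if isinstance(partial, SequenceRecord)
        else SequenceRecord(id="query", residues=str(partial))
    )
    view = _make_view(rec, ref, config)
    gviews = []
    for h in group_haplotypes:
        hrec = h if isinstance(h, SequenceRecord) else SequenceRecord(id="g", residues=str(h))
        try:
            gviews.append(_make_view(hrec, ref, config))
        except UnalignableError:
            continue
    consensus = _consensus_from_views(gviews, ref) if gviews else None
    decoy_views = _decoy_projections(decoys or [], ref, config)
    return _criterion_iii_view(
        view, consensus, len(gviews), ref, decoy_views, config
    )


def _decoy_projections(
    decoys: list, reference: str, config: ScreenConfig
) -> list[tuple[str, np.ndarray]]:
    out = []
    for d in decoys:
        rec = d if isinstance(d, SequenceRecord) else SequenceRecord(id="decoy", residues=str(d))
        try:
            v = _make_view(rec, reference, replace(config, min_identity=0.0))
        except UnalignableError:
            continue
        out.append((rec.id, v.proj))
    return out


def screen_criterion_iv(
    partial,
    reference,
    panel: ReferencePanel,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> tuple[bool, list[int], str]:
    """Criterion iv: amino-acid substitutions at panel-conserved
    positions. Returns (flag, violated 1-based panel columns, status);
    status is "too_short" when the translation is under the assessable
    minimum, in which case the flag is False."""
    ref = _residues(reference)
    mapped = map_partial_to_reference(
        _residues(partial), ref, config.scoring, config.min_identity
    )
    return _criterion_iv_mapped(_residues(partial), mapped, panel, config)


def _criterion_iv_mapped(
    seq: str, mapped: MappedPartial, panel: ReferencePanel, config: ScreenConfig
) -> tuple[bool, list[int], str]:
    lead = (3 - mapped.frame_offset) % 3
    aa = translate_mt(seq[lead:], config.genetic_code)
    if len(aa) < config.min_aa_len:
        return False, [], "too_short"
    codon0 = (mapped.ref_offset + lead - 1) // 3  # 0-based codon index
    violated: list[int] = []
    for k, res in enumerate(aa):
        col = codon0 + k
        if col >= len(panel):
            break
        if res in ("X", "*"):
            continue
        if panel.conserved_mask[col] and res != panel.conserved_residues[col]:
            violated.append(col + 1)
    return bool(violated), violated, "ok"


def screen_dataset(
    records: list[SequenceRecord],
    reference_by_group: dict[str, SequenceRecord | str],
    panel: ReferencePanel | None = None,
    decoys: list | None = None,
    config: ScreenConfig = DEFAULT_CONFIG,
) -> tuple[ScreenReport, dict[str, CriterionFlags]]:
    """Run the four-criterion screen over grouped haplotypes.

    Every record needs a group label and every group its own full-length
    reference gene. Per-criterion counts are raw (a haplotype may appear
    in several columns) while the union counts each haplotype once;
    unalignable records are listed and excluded from the counts. Groups
    with zero haplotypes are omitted.
    """
    by_group: dict[str, list[SequenceRecord]] = {}
    for rec in records:
        if rec.group is None:
            raise ScreenError(f"record {rec.id!r} has no group label")
        by_group.setdefault(rec.group, []).append(rec)

    report_groups: dict[str, GroupCounts] = {}
    unalignable: list[tuple[str, str]] = []
    flags_out: dict[str, CriterionFlags] = {}

    for group, members in by_group.items():
        if group not in reference_by_group:
            raise ScreenError(f"no reference gene supplied for group {group!r}")
        reference = _residues(reference_by_group[group])
        views: list[_View] = []
        for rec in members:
            try:
                views.append(_make_view(rec, reference, config))
            except UnalignableError as exc:
                unalignable.append((rec.id, str(exc)))
        if not views:
            continue
        consensus = _consensus_from_views(views, reference)
        decoy_views = _decoy_projections(decoys or [], reference, config)

        counts = dict.fromkeys(("i", "ii", "iii", "iv"), 0)
        union = 0
        for v in views:
            fl = CriterionFlags(haplotype_id=v.record.id)
            events = call_indels(v.mapped)
            if events:
                fl.flag_i = True
                for ev in events:
                    fl.evidence.append(
                        (
                            "i",
                            f"{ev.kind} of {ev.residues!r} ({ev.length} bp)",
                            f"after reference position {ev.ref_position}"
                            + (
                                f" (homopolymer run {ev.homopolymer_len} bp)"
                                if ev.homopolymer_len > 1
                                else ""
                            ),
                        )
                    )
            fl.analysed_at_aa_level = not fl.flag_i
            if fl.analysed_at_aa_level:
                hit, stops = screen_criterion_ii(
                    v.record,
                    v.mapped.frame_offset,
                    config,
                    ref_offset=v.mapped.ref_offset,
                    reference_length=len(reference),
                )
                if hit:
                    fl.flag_ii = True
                    fl.evidence.append(
                        (
                            "ii",
                            "premature stop codon(s)",
                            "reference codon starts " + ",".join(map(str, stops)),
                        )
                    )
            hit3, ev3 = _criterion_iii_view(
                v, consensus, len(views), reference, decoy_views, config
            )
            if hit3:
                fl.flag_iii = True
            fl.evidence.extend(("iii", what, detail) for what, detail in ev3)
            if panel is not None and fl.analysed_at_aa_level and not fl.flag_ii:
                hit4, cols, status = _criterion_iv_mapped(
                    v.record.residues, v.mapped, panel, config
                )
                if status == "too_short":
                    fl.evidence.append(("iv", "too short to assess", ""))
                elif hit4:
                    fl.flag_iv = True
                    fl.evidence.append(
                        (
                            "iv",
                            "substitution at conserved panel position(s)",
                            ",".join(map(str, cols)),
                        )
                    )
            for key, val in (
                ("i", fl.flag_i),
                ("ii", fl.flag_ii),
                ("iii", fl.flag_iii),
                ("iv", fl.flag_iv),
            ):
                counts[key] += int(val)
            union += int(fl.any_flag)
            flags_out[v.record.id] = fl
        report_groups[group] = GroupCounts(
            total=len(views),
            count_i=counts["i"],
            count_ii=counts["ii"],
            count_iii=counts["iii"],
            count_iv=counts["iv"],
            union=union,
        )
    return ScreenReport(groups=report_groups, unalignable=unalignable), flags_out


def write_evidence_tsv(flags: dict[str, CriterionFlags], path) -> None:
    """Per-haplotype evidence table (haplotype id, criterion,
    description, coordinates)."""
    with open(path, "w") as fh:
        fh.write("haplotype\tcriterion\tdescription\tcoordinates\n")
        for hid, fl in flags.items():
            for item in fl.evidence:
                crit, desc, coords = (item if len(item) == 3 else (*item, ""))
                fh.write(f"{hid}\t{crit}\t{desc}\t{coords}\n")
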