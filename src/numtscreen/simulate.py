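"""Synthetic barcode datasets with known truth labels.

The generator emulates the inputs the screening and divergence analyses
assume: a full-length protein-coding mitochondrial gene, groups of
closely related haplotypes evolved from group ancestors under a
Jukes-Cantor substitution process with purifying constraint (mutations
at conserved codons are restricted to synonymous changes, and no
internal stop codons arise), optional region-heterogeneous rates along
the gene (to plant 5'/3' divergence contrast), and NUMT-like corrupted
copies carrying one of five lesion classes: interior INDELs
(homopolymer-biased), premature stop codons, terminal clusters of
non-synonymous substitutions, globally divergent copies that ignore
codon constraint, and chimeras spliced with a foreign decoy sequence.

Groups follow a star phylogeny: each group ancestor sits at half the
group's sibling-divergence target from a shared root, and each
haplotype at half the within-group target from its ancestor, so
realised pairwise divergences match the targets in expectation. All
output is reproducible from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml
from Bio.Data import CodonTable

from .screen import ReferencePanel, _code, build_reference_panel
from .seqio import SequenceRecord, write_fasta


class SimulationError(ValueError):
    """Raised on invalid or unattainable simulation settings."""


@dataclass(frozen=True)
class GroupSpec:
    """One haplotype group: ``within`` and ``to_sibling`` are target
    pairwise divergences (substitutions/site); ``rate_profile``
    overrides the config-level profile for this group's ancestor."""

    name: str
    n: int
    within: float
    to_sibling: float
    rate_profile: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise SimulationError(f"group {self.name}: n must be >= 1")
        for label, v in (("within", self.within), ("to_sibling", self.to_sibling)):
            if not 0.0 <= v < 0.5:
                raise SimulationError(
                    f"group {self.name}: {label} divergence {v} outside [0, 0.5)"
                )


@dataclass(frozen=True)
class NumtSpec:
    """Counts and lesion parameters per NUMT class."""

    indel: int = 10
    stop: int = 10
    terminal_cluster: int = 10
    global_divergent: int = 10
    decoy_chimera: int = 5
    indel_max_len: int = 4          # bp; interior indels of 1..max bp
    cluster_len_range: tuple[int, int] = (9, 116)  # bp terminal stretch
    cluster_sub_density: float = 0.25  # non-synonymous subs per bp in stretch
    global_rate: float = 0.053      # per-site substitution prob, unconstrained
    chimera_splice_frac: float = 1.0 / 3.0  # parent fraction kept at the 5' end

    def __post_init__(self) -> None:
        for name in ("indel", "stop", "terminal_cluster", "global_divergent", "decoy_chimera"):
            if getattr(self, name) < 0:
                raise SimulationError(f"numt count {name} must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic dataset.

    Defaults: a 514-codon gene (1,542 bp), three groups patterned on the
    Mediterranean whitefly subclades (two close siblings plus one group
    near the delimitation boundary), 60% of codons under absolute
    amino-acid constraint, a 12-protein reference panel, and ten NUMTs
    per deterministic lesion class.
    """

    seed: int = 0
    n_codons: int = 514
    conserved_fraction: float = 0.6
    rate_profile: tuple[float, ...] = (1.0,)
    groups: tuple[GroupSpec, ...] = (
        GroupSpec(name="Q1", n=14, within=0.008, to_sibling=0.012),
        GroupSpec(name="Q2", n=12, within=0.008, to_sibling=0.012),
        GroupSpec(name="ASL", n=10, within=0.006, to_sibling=0.032),
    )
    partial_region: tuple[int, int] = (783, 1439)
    n_panel: int = 12
    panel_variant_prob: float = 0.3
    n_decoys: int = 2
    decoy_divergence: float = 0.12
    numts: NumtSpec = NumtSpec()

    def __post_init__(self) -> None:
        if not 0.0 <= self.conserved_fraction <= 1.0:
            raise SimulationError("conserved_fraction outside [0, 1]")
        if self.n_codons < 3:
            raise SimulationError("gene must have at least 3 codons")
        s, e = self.partial_region
        if not 1 <= s <= e <= 3 * self.n_codons:
            raise SimulationError("partial_region outside the gene")

    @property
    def gene_length(self) -> int:
        return 3 * self.n_codons

    def to_yaml(self, path=None) -> str:
        d = asdict(self)
        text = yaml.safe_dump(d, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimConfig":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = yaml.safe_load(text)
        d["groups"] = tuple(
            GroupSpec(**{**g, "rate_profile": tuple(g["rate_profile"]) if g.get("rate_profile") else None})
            for g in d.get("groups", [])
        )
        d["numts"] = NumtSpec(
            **{
                **d.get("numts", {}),
                "cluster_len_range": tuple(d["numts"]["cluster_len_range"]),
            }
        )
        d["rate_profile"] = tuple(d.get("rate_profile", (1.0,)))
        d["partial_region"] = tuple(d["partial_region"])
        return cls(**d)


@dataclass
class TruthRow:
    id: str
    group: str
    cls: str  # "authentic" | "numt:<class>"
    lesion: str = ""


@dataclass
class SimTruth:
    rows: list[TruthRow] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("id\tgroup\tclass\tlesion\n")
            for r in self.rows:
                fh.write(f"{r.id}\t{r.group}\t{r.cls}\t{r.lesion}\n")

    def by_class(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for r in self.rows:
            out.setdefault(r.cls, []).append(r.id)
        return out


_BASES = "ACGT"


def _rng(config: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, *key])


def _non_stop_codons(code_id: int = 5) -> list[str]:
    table = CodonTable.unambiguous_dna_by_id[code_id]
    return [c for c in sorted(table.forward_table) if c not in table.stop_codons]


def conserved_codon_set(config: SimConfig) -> frozenset[int]:
    """The codons (0-based indices) whose amino acid is immutable in
    authentic sequences; deterministic given the seed, shared between
    the haplotype generator and the panel builder."""
    rng = _rng(config, 1)
    k = int(round(config.conserved_fraction * (config.n_codons - 1)))
    chosen = rng.choice(np.arange(1, config.n_codons), size=k, replace=False)
    return frozenset(int(c) for c in chosen)


def simulate_reference_gene(config: SimConfig) -> SequenceRecord:
    """A random codon sequence with an ATG start and no internal stop
    under the invertebrate mitochondrial code; deterministic per seed."""
    rng = _rng(config, 0)
    codons = _non_stop_codons()
    idx = rng.integers(0, len(codons), size=config.n_codons - 1)
    seq = "ATG" + "".join(codons[i] for i in idx)
    return SequenceRecord(id="root_reference", residues=seq)


def _profile_weights(L: int, profile: tuple[float, ...]) -> np.ndarray:
    k = len(profile)
    seg = np.minimum((np.arange(L) * k) // L, k - 1)
    return np.asarray(profile, dtype=float)[seg]


def _site_options(
    seq: str, conserved: frozenset[int], code_id: int = 5
) -> list[str]:
    """Per-site string of allowed alternative bases: synonymous-only at
    conserved codons, any non-stop-producing change elsewhere."""
    code = _code(code_id)
    out: list[str] = []
    for i, base in enumerate(seq):
        ci = i // 3
        pos = i % 3
        cod = seq[3 * ci : 3 * ci + 3]
        opts = []
        if len(cod) == 3 and all(b in _BASES for b in cod):
            for b in _BASES:
                if b == base:
                    continue
                alt = cod[:pos] + b + cod[pos + 1 :]
                if code[alt] == "*":
                    continue
                if ci in conserved and code[alt] != code[cod]:
                    continue
                opts.append(b)
        out.append("".join(opts))
    return out


def mutate_constrained(
    seq: str,
    target_p: float,
    rng: np.random.Generator,
    conserved: frozenset[int],
    weights: np.ndarray | None = None,
    code_id: int = 5,
) -> str:
    """Evolve ``seq`` by Jukes-Cantor-style substitutions with expected
    mismatch fraction ``target_p`` over the full length, respecting the
    protein constraint. Raises when the target cannot be reached within
    the constraint."""
    L = len(seq)
    if target_p == 0.0:
        return seq
    options = _site_options(seq, conserved, code_id)
    elig = np.array([i for i, o in enumerate(options) if o], dtype=int)
    if elig.size == 0:
        raise SimulationError("no mutable sites under the constraint")
    n_mut = int(round(target_p * L))
    if n_mut > elig.size:
        raise SimulationError(
            f"divergence target {target_p} unattainable under the protein "
            "constraint; lower the target"
        )
    if n_mut == 0:
        return seq
    w = np.ones(L) if weights is None else np.asarray(weights, dtype=float)
    we = w[elig]
    # substitution count fixed at the target expectation; sites drawn
    # without replacement with profile-proportional weights
    hits = rng.choice(elig, size=n_mut, replace=False, p=we / we.sum())
    new = list(seq)
    mutated_by_codon: dict[int, list[int]] = {}
    for i in hits:
        opts = options[i]
        new[i] = opts[rng.integers(len(opts))]
        mutated_by_codon.setdefault(i // 3, []).append(int(i))
    # repair codons whose combined substitutions break the constraint
    code = _code(code_id)
    for ci, sites in mutated_by_codon.items():
        sites.sort()
        while sites:
            cod = "".join(new[3 * ci : 3 * ci + 3])
            old = seq[3 * ci : 3 * ci + 3]
            bad = code[cod] == "*" or (ci in conserved and code[cod] != code[old])
            if not bad:
                break
            i = sites.pop()
            new[i] = seq[i]
    return "".join(new)


def mutate_unconstrained(
    seq: str, rate: float, rng: np.random.Generator
) -> tuple[str, list[int]]:
    """Uniform per-site substitution ignoring codon constraint (the
    NUMT evolutionary regime); returns the sequence and 1-based mutated
    positions."""
    new = list(seq)
    hit_sites: list[int] = []
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for i in hits:
        alts = [b for b in _BASES if b != seq[i]]
        if seq[i] not in _BASES:
            continue
        new[i] = alts[rng.integers(3)]
        hit_sites.append(int(i) + 1)
    return "".join(new), hit_sites


@dataclass
class GroupSet:
    """Authentic haplotypes plus the group ancestors they evolved from."""

    records: list[SequenceRecord]
    ancestors: dict[str, SequenceRecord]
    truth: SimTruth


def simulate_groups(reference: SequenceRecord, config: SimConfig) -> GroupSet:
    """Evolve group ancestors from the root and star-phylogeny
    haplotypes from each ancestor (full-length sequences)."""
    conserved = conserved_codon_set(config)
    records: list[SequenceRecord] = []
    ancestors: dict[str, SequenceRecord] = {}
    truth = SimTruth()
    for k, spec in enumerate(config.groups):
        rng = _rng(config, 2, k)
        profile = spec.rate_profile or config.rate_profile
        weights = _profile_weights(len(reference.residues), profile)
        anc_seq = mutate_constrained(
            reference.residues, spec.to_sibling / 2.0, rng, conserved, weights
        )
        ancestors[spec.name] = SequenceRecord(
            id=f"{spec.name}_ancestor", residues=anc_seq, group=spec.name
        )
        for j in range(spec.n):
            hap = mutate_constrained(
                anc_seq, spec.within / 2.0, rng, conserved, weights
            )
            rid = f"{spec.name}_h{j + 1}"
            records.append(SequenceRecord(id=rid, residues=hap, group=spec.name))
            truth.rows.append(TruthRow(id=rid, group=spec.name, cls="authentic"))
    return GroupSet(records=records, ancestors=ancestors, truth=truth)


def _find_homopolymer_runs(seq: str, margin: int) -> list[tuple[int, int]]:
    """(start, length) of homopolymer runs (length >= 2) in the interior
    [margin, len-margin); 0-based starts."""
    runs = []
    i = margin
    stop_at = len(seq) - margin
    while i < stop_at:
        j = i
        while j + 1 < stop_at and seq[j + 1] == seq[i]:
            j += 1
        if j > i:
            runs.append((i, j - i + 1))
        i = j + 1
    return runs


def _lesion_indel(seq: str, rng, spec: NumtSpec, region_start: int) -> tuple[str, str]:
    margin = 30
    length = int(rng.integers(1, spec.indel_max_len + 1))
    runs = _find_homopolymer_runs(seq, margin)
    if runs and rng.random() < 0.8:
        pos, _run_len = runs[int(rng.integers(len(runs)))]
    else:
        pos = int(rng.integers(margin, len(seq) - margin - length))
    if rng.random() < 0.5 and pos + length < len(seq) - margin:
        removed = seq[pos : pos + length]
        new = seq[:pos] + seq[pos + length :]
        desc = f"deletion of {removed!r} after reference position {region_start + pos - 1}"
    else:
        inserted = seq[pos] * length
        new = seq[: pos + 1] + inserted + seq[pos + 1 :]
        desc = f"insertion of {inserted!r} after reference position {region_start + pos}"
    return new, desc


def _lesion_stop(seq: str, rng, region_start: int) -> tuple[str, str]:
    frame = (region_start - 1) % 3
    lead = (3 - frame) % 3
    n_codons = (len(seq) - lead) // 3
    k = int(rng.integers(n_codons // 6, 5 * n_codons // 6))
    start = lead + 3 * k
    stop = "TAA" if rng.random() < 0.5 else "TAG"
    new = seq[:start] + stop + seq[start + 3 :]
    return new, f"premature stop {stop} at reference codon start {region_start + start}"


def _lesion_cluster(
    seq: str, rng, spec: NumtSpec, reference: str, region_start: int
) -> tuple[str, str]:
    lo, hi = spec.cluster_len_range
    slen = int(rng.integers(lo, min(hi, len(seq)) + 1))
    at_5prime = bool(rng.random() < 0.5)
    offsets = np.arange(slen) if at_5prime else np.arange(len(seq) - slen, len(seq))
    n_subs = max(2, math.ceil(slen * spec.cluster_sub_density))
    chosen = rng.choice(offsets, size=min(n_subs, slen), replace=False)
    new = list(seq)
    planted = 0
    code5 = _code(5)
    for pos in sorted(int(c) for c in chosen):
        ref_pos = region_start + pos
        ref_base = reference[ref_pos - 1]
        candidates = []
        for b in _BASES:
            if b in (seq[pos], ref_base):
                continue
            ci = (ref_pos - 1) // 3
            cod = reference[3 * ci : 3 * ci + 3]
            p = (ref_pos - 1) % 3
            alt = cod[:p] + b + cod[p + 1 :]
            if code5[alt] == "*" or code5[alt] == code5[cod]:
                continue
            candidates.append(b)
        if not candidates:
            continue
        new[pos] = candidates[int(rng.integers(len(candidates)))]
        planted += 1
    end = "5'" if at_5prime else "3'"
    return (
        "".join(new),
        f"{planted} non-synonymous substitutions in a {slen} bp stretch at the {end} end",
    )


def simulate_numts(
    parents: list[SequenceRecord],
    reference_by_group: dict[str, SequenceRecord],
    config: SimConfig,
    decoys: list[SequenceRecord] | None = None,
) -> tuple[list[SequenceRecord], SimTruth]:
    """Derive NUMT-like corrupted copies from authentic partial
    haplotypes; every lesion is recorded in the truth table."""
    if not parents:
        raise SimulationError("no parent haplotypes supplied")
    spec = config.numts
    rng = _rng(config, 3)
    region_start = config.partial_region[0]
    records: list[SequenceRecord] = []
    truth = SimTruth()
    classes: list[tuple[str, int]] = [
        ("indel", spec.indel),
        ("stop", spec.stop),
        ("terminal-cluster", spec.terminal_cluster),
        ("global-divergent", spec.global_divergent),
        ("decoy-chimera", spec.decoy_chimera),
    ]
    if spec.decoy_chimera > 0 and not decoys:
        raise SimulationError("decoy-chimera NUMTs requested but no decoys supplied")
    counter = 0
    for cls, count in classes:
        for _ in range(count):
            counter += 1
            parent = parents[int(rng.integers(len(parents)))]
            reference = reference_by_group[parent.group].residues
            if cls == "indel":
                seq, desc = _lesion_indel(parent.residues, rng, spec, region_start)
            elif cls == "stop":
                seq, desc = _lesion_stop(parent.residues, rng, region_start)
            elif cls == "terminal-cluster":
                seq, desc = _lesion_cluster(
                    parent.residues, rng, spec, reference, region_start
                )
            elif cls == "global-divergent":
                seq, sites = mutate_unconstrained(
                    parent.residues, spec.global_rate, rng
                )
                desc = f"{len(sites)} substitutions ignoring codon constraint"
            else:  # decoy-chimera
                decoy = decoys[int(rng.integers(len(decoys)))]
                splice = int(len(parent.residues) * spec.chimera_splice_frac)
                seq = parent.residues[:splice] + decoy.residues[splice:]
                desc = f"spliced with {decoy.id} from partial position {splice + 1}"
            rid = f"NUMT_{cls}_{counter}"
            records.append(SequenceRecord(id=rid, residues=seq, group=parent.group))
            truth.rows.append(
                TruthRow(
                    id=rid,
                    group=parent.group,
                    cls=f"numt:{cls}",
                    lesion=f"parent={parent.id}; {desc}",
                )
            )
    return records, truth


def simulate_decoys(
    reference_partial: SequenceRecord, config: SimConfig
) -> list[SequenceRecord]:
    """Foreign-looking decoy sequences (a stand-in for other-species or
    chloroplast accessions) at the configured divergence from the
    reference barcode region."""
    rng = _rng(config, 4)
    out = []
    for i in range(config.n_decoys):
        seq, _ = mutate_unconstrained(
            reference_partial.residues, config.decoy_divergence, rng
        )
        out.append(SequenceRecord(id=f"decoy_{i + 1}", residues=seq))
    return out


def simulate_panel(reference: SequenceRecord, config: SimConfig) -> list[str]:
    """Reference protein panel: the root translation plus variants that
    mutate only at non-conserved codons, with every non-conserved column
    guaranteed to vary (so the panel's conserved mask equals the
    generator's conserved-codon truth)."""
    from .screen import translate_mt

    rng = _rng(config, 5)
    conserved = conserved_codon_set(config)
    base = translate_mt(reference.residues)
    aa_alphabet = "ACDEFGHIKLMNPQRSTVWY"
    rows = [base]
    for _ in range(config.n_panel - 1):
        row = list(base)
        for ci in range(len(base)):
            if ci in conserved:
                continue
            if rng.random() < config.panel_variant_prob:
                alts = [a for a in aa_alphabet if a != base[ci]]
                row[ci] = alts[int(rng.integers(len(alts)))]
        rows.append("".join(row))
    # guarantee variation at every non-conserved column
    for ci in range(len(base)):
        if ci in conserved:
            continue
        if len({r[ci] for r in rows}) == 1:
            alts = [a for a in aa_alphabet if a != base[ci]]
            pick = alts[int(rng.integers(len(alts)))]
            rows[1] = rows[1][:ci] + pick + rows[1][ci + 1 :]
    return rows


@dataclass
class SimDataset:
    """A full synthetic study: inputs, references, panel and truth."""

    config: SimConfig
    reference: SequenceRecord
    group_ancestors: dict[str, SequenceRecord]
    full_records: list[SequenceRecord]
    partials: list[SequenceRecord]
    numts: list[SequenceRecord]
    decoys: list[SequenceRecord]
    panel_proteins: list[str]
    truth: SimTruth

    @property
    def records(self) -> list[SequenceRecord]:
        """The study input: authentic partial haplotypes plus NUMTs."""
        return self.partials + self.numts

    @property
    def panel(self) -> ReferencePanel:
        return build_reference_panel(self.panel_proteins)


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Generate the complete labelled dataset for one configuration."""
    reference = simulate_reference_gene(config)
    groups = simulate_groups(reference, config)
    s, e = config.partial_region
    partials = [
        SequenceRecord(id=r.id, residues=r.residues[s - 1 : e], group=r.group)
        for r in groups.records
    ]
    ref_partial = SequenceRecord(
        id="root_partial", residues=reference.residues[s - 1 : e]
    )
    decoys = simulate_decoys(ref_partial, config)
    numts, numt_truth = simulate_numts(
        partials, groups.ancestors, config, decoys=decoys
    )
    truth = SimTruth(rows=groups.truth.rows + numt_truth.rows)
    panel_rows = simulate_panel(reference, config)
    return SimDataset(
        config=config,
        reference=reference,
        group_ancestors=groups.ancestors,
        full_records=groups.records,
        partials=partials,
        numts=numts,
        decoys=decoys,
        panel_proteins=panel_rows,
        truth=truth,
    )


def emit_fixture(
    records: list[SequenceRecord],
    truth: SimTruth,
    outdir: str | Path,
    config: SimConfig,
) -> list[Path]:
    """Write the dataset FASTA (group in description), the truth TSV and
    the generating config; regenerating from the echoed config is
    byte-identical."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fasta = outdir / "dataset.fasta"
    truth_tsv = outdir / "truth.tsv"
    config_yaml = outdir / "config.yaml"
    write_fasta(records, fasta)
    truth.to_tsv(truth_tsv)
    config.to_yaml(config_yaml)
    return [fasta, truth_tsv, config_yaml]


def asl_scenario_config(seed: int = 0) -> SimConfig:
    """A two-group scenario around the species boundary: a 5'-hot rate
    profile places the between-group divergence above 3.5% in the 5'
    barcode while the 3' barcode stays below it."""
    return SimConfig(
        seed=seed,
        rate_profile=(2.0, 1.0),
        groups=(
            GroupSpec(name="MED", n=2, within=0.004, to_sibling=0.033),
            GroupSpec(name="ASL", n=2, within=0.004, to_sibling=0.033),
        ),
        numts=NumtSpec(
            indel=0, stop=0, terminal_cluster=0, global_divergent=0, decoy_chimera=0
        ),
        n_decoys=0,
    )
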