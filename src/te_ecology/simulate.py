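"""Synthetic toy-genome generator with known ground truth.

Builds a small multi-chromosome genome carrying TE copies from all 13 plant
superfamilies, with nested insertions of known arrival order, sequences
diverged from family ancestors under a known per-site substitution rate
(transition:transversion 2:1, so the K2P estimator is exactly matched),
paired-LTR alignments, per-superfamily trees whose terminal branches encode
the true ages, and methylation / expression / genetic-map / chromatin /
variant / subgenome layers with configurable family-level structure.

Every downstream stage of the package can be exercised on this dataset with
no external inputs, and estimator accuracy can be checked against the truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .ages import MU_MAIZE
from .annotation import TECopy
from .taxonomy import LTR_SUPERFAMILIES, SUPERFAMILIES

__all__ = [
    "SimConfig",
    "SyntheticDataset",
    "CapacityError",
    "generate_dataset",
    "generate_family_alignments",
    "generate_age_features",
    "simulate_ltr_pairs",
]

BASES = np.frombuffer(b"ACGT", dtype="S1")
#: transition partner of each base
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

DEFAULT_TISSUES = ("anther", "SAM", "earshoot", "flagleaf", "seedling_leaf")


class CapacityError(ValueError):
    """The requested TE load cannot be packed into the genome."""


@dataclass
class SimConfig:
    """Study conditions for the toy genome.

    ``mu`` is the maize per-year point substitution rate; family sizes follow
    a truncated zipf (heavy-tailed, like real TE family-size distributions);
    ``age_effect_spec`` parameterizes the model-recovery harness
    (:func:`generate_age_features`), mapping feature name to
    (shape, coefficient) with shapes linear / quadratic / threshold.
    """

    seed: int = 0
    n_chromosomes: int = 3
    chrom_length: int = 250_000
    n_families_per_superfamily: int = 2
    family_size_distribution: dict = field(
        default_factory=lambda: {"zipf_a": 1.8, "max_size": 20}
    )
    nesting_probability: float = 0.2
    mu: float = MU_MAIZE
    age_effect_spec: dict = field(
        default_factory=lambda: {
            "meth_cg_te": ("linear", 4.0e5),
            "length_bp": ("quadratic", 2.0e5),
            "family_rpm": ("threshold", -2.5e5),
        }
    )
    noise_sd: float = 5.0e4
    tissue_names: tuple[str, ...] = DEFAULT_TISSUES
    ltr_length: int = 300
    max_element_length: int = 4000

    def validate(self) -> None:
        if not (0.0 <= self.nesting_probability <= 1.0):
            raise ValueError("nesting_probability must lie in [0, 1]")
        if self.mu <= 0:
            raise ValueError("mu must be positive")
        if self.chrom_length < 10 * self.max_element_length:
            raise CapacityError(
                "chrom_length must be at least 10x the maximum element length"
            )
        if self.n_chromosomes < 1 or self.n_families_per_superfamily < 1:
            raise ValueError("counts must be positive")


@dataclass
class SyntheticDataset:
    config: SimConfig
    te_copies: list[TECopy]
    genes: pd.DataFrame
    genome: dict[str, str]
    true_ages: dict[str, float]
    arrival_order: list[str]
    trees: dict[str, str]
    ltr_alignments: dict[str, tuple[str, str]]
    methylation: pd.DataFrame
    te_counts: pd.DataFrame
    library_sizes: pd.DataFrame
    gene_expression: pd.DataFrame
    genetic_map: pd.DataFrame
    mnase: dict[str, pd.DataFrame]
    variants: pd.DataFrame
    subgenomes: pd.DataFrame
    domain_hits: pd.DataFrame
    family_truth: pd.DataFrame

    # ------------------------------------------------------------------ io
    def write(self, outdir: str | Path) -> Path:
        """Serialize every layer to standard text formats (GFF3/FASTA/BED/
        TSV/newick/JSON) under ``outdir``."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)

        with open(out / "te.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            order_index = {cid: i for i, cid in enumerate(self.arrival_order)}
            for c in sorted(self.te_copies, key=lambda c: (c.chrom, c.start, c.copy_id)):
                attrs = (
                    f"ID={c.copy_id};family={c.family_id};superfamily={c.superfamily}"
                    f";arrival_index={order_index[c.copy_id]}"
                )
                if c.parent_te:
                    attrs += f";parent_te={c.parent_te}"
                fh.write(
                    f"{c.chrom}\tsim\ttransposable_element\t{c.start + 1}\t{c.end}"
                    f"\t.\t{c.strand}\t.\t{attrs}\n"
                )
        with open(out / "genes.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for _, g in self.genes.iterrows():
                fh.write(
                    f"{g.chrom}\tsim\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}"
                    f"\t.\tID={g.gene_id}\n"
                )
        if "syntenic" in self.genes.columns:
            (out / "syntenic_genes.txt").write_text(
                "".join(f"{g}\n" for g in self.genes.loc[self.genes["syntenic"],
                                                         "gene_id"])
            )
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.genome):
                fh.write(f">{chrom}\n")
                seq = self.genome[chrom]
                for i in range(0, len(seq), 80):
                    fh.write(seq[i : i + 80] + "\n")
        treedir = out / "trees"
        treedir.mkdir(exist_ok=True)
        for sf in sorted(self.trees):
            (treedir / f"{sf}.nwk").write_text(self.trees[sf] + "\n")
        with open(out / "ltr_alignments.fasta", "w") as fh:
            for cid in sorted(self.ltr_alignments):
                five, three = self.ltr_alignments[cid]
                fh.write(f">{cid}_5LTR\n{five}\n>{cid}_3LTR\n{three}\n")
        self.methylation.to_csv(out / "methylation_windows.tsv", sep="\t", index=False)
        self.te_counts.to_csv(out / "te_counts.tsv", sep="\t", index=False)
        self.library_sizes.to_csv(out / "library_sizes.tsv", sep="\t", index=False)
        self.gene_expression.to_csv(out / "gene_expression.tsv", sep="\t", index=False)
        self.genetic_map.to_csv(out / "genetic_map.tsv", sep="\t", index=False)
        for tissue, df in sorted(self.mnase.items()):
            df.to_csv(
                out / f"mnase_{tissue}.bed", sep="\t", index=False, header=False,
                columns=["chrom", "start", "end"],
            )
        self.variants.to_csv(out / "variants.tsv", sep="\t", index=False)
        self.subgenomes.to_csv(
            out / "subgenomes.bed", sep="\t", index=False, header=False,
            columns=["chrom", "start", "end", "subgenome"],
        )
        self.domain_hits.to_csv(out / "domain_hits.tsv", sep="\t", index=False)
        truth = {
            "true_ages": {k: float(v) for k, v in sorted(self.true_ages.items())},
            "arrival_order": self.arrival_order,
            "mu": self.config.mu,
            "seed": self.config.seed,
        }
        (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
        self.family_truth.to_csv(out / "family_truth.tsv", sep="\t", index=False)
        cfg = dataclasses.asdict(self.config)
        cfg["tissue_names"] = list(cfg["tissue_names"])
        (out / "sim_config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
        return out

    def chrom_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.genome.items()}


# --------------------------------------------------------------------------
# sequence helpers


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p).tobytes().decode()


def _deaminate(rng: np.random.Generator, seq: str, level: float) -> str:
    """Convert a fraction of CG dinucleotides to TG (or CA on the other
    strand), emulating deamination of methylated cytosines."""
    s = list(seq)
    i = 0
    while i < len(s) - 1:
        if s[i] == "C" and s[i + 1] == "G" and rng.random() < level:
            if rng.random() < 0.5:
                s[i] = "T"  # CG -> TG
            else:
                s[i + 1] = "A"  # CG -> CA
            i += 2
        else:
            i += 1
    return "".join(s)


def _mutate(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Apply ``n_subs`` substitutions at distinct sites, ts:tv = 2:1."""
    if n_subs == 0:
        return seq
    s = list(seq)
    sites = rng.choice(len(s), size=min(n_subs, len(s)), replace=False)
    for i in sites:
        base = s[i]
        if base not in TRANSITION:
            continue
        if rng.random() < 2.0 / 3.0:
            s[i] = TRANSITION[base]
        else:
            s[i] = TRANSVERSIONS[base][rng.integers(2)]
    return "".join(s)


def simulate_ltr_pairs(
    ages: np.ndarray, mu: float, ltr_len: int, seed: int
) -> dict[str, tuple[str, str]]:
    """Simulate paired LTRs for copies of given true ages: both LTRs start
    identical and each accumulates Binomial(L, mu*age) substitutions."""
    rng = np.random.default_rng(seed)
    out = {}
    for i, age in enumerate(np.asarray(ages, dtype=float)):
        if age < 0:
            raise ValueError("ages must be non-negative")
        anc = _random_seq(rng, ltr_len)
        p = min(1.0, mu * age)
        five = _mutate(rng, anc, int(rng.binomial(ltr_len, p)))
        three = _mutate(rng, anc, int(rng.binomial(ltr_len, p)))
        out[f"sim{i:05d}"] = (five, three)
    return out


def generate_family_alignments(
    n_copies: int, true_ages, mu: float, seed: int, length: int = 1000
) -> tuple[dict[str, str], str]:
    """Aligned copy sequences plus a newick tree for one family.

    Stands in for an external aligner/tree builder: copies are simulated from
    a common ancestor with Binomial(L, mu*age) substitutions each, and the
    emitted star tree carries terminal branch lengths mu*age exactly — the
    simulation writes the truth directly.
    """
    ages = np.asarray(true_ages, dtype=float)
    if n_copies < 2 or len(ages) != n_copies:
        raise ValueError("need n_copies >= 2 ages")
    if np.any(ages < 0):
        raise ValueError("ages must be non-negative")
    rng = np.random.default_rng(seed)
    anc = _random_seq(rng, length)
    seqs = {}
    labels = [f"cp{i:05d}" for i in range(n_copies)]
    for label, age in zip(labels, ages):
        n = int(rng.binomial(length, min(1.0, mu * age)))
        seqs[label] = _mutate(rng, anc, n)
    newick = "(" + ",".join(
        f"{lbl}:{mu * age:.10f}" for lbl, age in zip(labels, ages)
    ) + ");"
    return seqs, newick


def _star_newick(ids: list[str], branch_lengths: list[float]) -> str:
    if len(ids) == 1:
        return f"({ids[0]}:{branch_lengths[0]:.10f});"
    return "(" + ",".join(
        f"{i}:{b:.10f}" for i, b in zip(ids, branch_lengths)
    ) + ");"


# --------------------------------------------------------------------------
# model-recovery harness


def generate_age_features(
    n: int,
    age_effect_spec: dict | None = None,
    noise_sd: float = 5.0e4,
    seed: int = 0,
    n_decoys: int = 47,
    base_age: float = 5.0e5,
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """Feature table with ages generated from a known function of a causal
    feature subset, plus independent decoy features.

    Effect shapes: ``linear`` (beta * x), ``quadratic`` (beta * x^2),
    ``threshold`` (beta * 1[x > 0]).  A categorical ``superfamily`` column
    (independent of age) is included so superfamily-level ICE summaries can
    be exercised.  Returns (features, ages, metadata echoing the effect
    specification so recovery tests can compare against the truth).
    """
    if n < 100:
        raise ValueError("n must be >= 100")
    if age_effect_spec is None:
        age_effect_spec = SimConfig().age_effect_spec
    rng = np.random.default_rng(seed)
    cols: dict[str, np.ndarray] = {}
    ages = np.full(n, base_age, dtype=float)
    for name, (shape, beta) in age_effect_spec.items():
        x = rng.normal(size=n)
        cols[name] = x
        if shape == "linear":
            ages += beta * x
        elif shape == "quadratic":
            ages += beta * x**2
        elif shape == "threshold":
            ages += beta * (x > 0)
        else:
            raise ValueError(f"unknown effect shape {shape!r}")
    for j in range(n_decoys):
        cols[f"decoy_{j:02d}"] = rng.normal(size=n)
    ages += rng.normal(scale=noise_sd, size=n) if noise_sd > 0 else 0.0
    feat = pd.DataFrame(cols)
    sfs = sorted(SUPERFAMILIES)
    feat["superfamily"] = pd.Categorical.from_codes(
        rng.integers(len(sfs), size=n), categories=sfs
    )
    meta = {
        "age_effect_spec": {k: list(v) for k, v in age_effect_spec.items()},
        "noise_sd": noise_sd,
        "n": n,
        "n_decoys": n_decoys,
        "seed": seed,
        "base_age": base_age,
    }
    return feat, pd.Series(ages, name="age_years"), meta


# --------------------------------------------------------------------------
# full dataset


@dataclass
class _FamilyPlan:
    family_id: str
    superfamily: str
    length: int
    ltr_len: int  # 0 for non-LTR
    consensus: str
    size: int
    mean_age: float
    deamination: float
    meth_level: dict[str, float]
    expr_rpm: float
    silenced: bool
    coding_capable: bool


_SF_LENGTH_RANGES = {
    "DHH": (800, 3500), "DTA": (300, 1500), "DTC": (1000, 3500),
    "DTH": (200, 800), "DTM": (500, 2500), "DTT": (150, 600),
    "DTX": (200, 1200), "RLC": (0, 0), "RLG": (0, 0), "RLX": (0, 0),
    "RIL": (1500, 3800), "RIT": (800, 2500), "RST": (120, 350),
}


def _plan_families(cfg: SimConfig, rng: np.random.Generator) -> list[_FamilyPlan]:
    dist = cfg.family_size_distribution
    plans: list[_FamilyPlan] = []
    fam_counter = 0
    for sf in sorted(SUPERFAMILIES):
        for _ in range(cfg.n_families_per_superfamily):
            fam_counter += 1
            family_id = f"{sf}{fam_counter:05d}"
            size = int(min(rng.zipf(dist.get("zipf_a", 1.6)), dist.get("max_size", 24)))
            size = max(size, 2)
            if sf in LTR_SUPERFAMILIES:
                ltr_len = cfg.ltr_length
                internal = int(rng.integers(600, min(2400, cfg.max_element_length - 2 * ltr_len)))
                length = 2 * ltr_len + internal
            else:
                lo, hi = _SF_LENGTH_RANGES[sf]
                hi = min(hi, cfg.max_element_length)
                ltr_len = 0
                length = int(rng.integers(lo, hi))
            deam = float(rng.uniform(0.0, 0.8))
            gc = float(rng.uniform(0.35, 0.55))
            if ltr_len:
                ltr = _deaminate(rng, _random_seq(rng, ltr_len, gc), deam)
                internal_seq = _deaminate(rng, _random_seq(rng, length - 2 * ltr_len, gc), deam)
                consensus = ltr + internal_seq + ltr
            else:
                consensus = _deaminate(rng, _random_seq(rng, length, gc), deam)
            meth = {
                "CG": float(np.clip(rng.normal(0.85, 0.08), 0.3, 0.98)),
                "CHG": float(np.clip(rng.normal(0.70, 0.10), 0.2, 0.95)),
                "CHH": float(np.clip(rng.normal(0.08, 0.04), 0.01, 0.4)),
            }
            silenced = bool(size >= 8 and rng.random() < 0.7)
            plans.append(
                _FamilyPlan(
                    family_id=family_id,
                    superfamily=sf,
                    length=length,
                    ltr_len=ltr_len,
                    consensus=consensus,
                    size=size,
                    mean_age=float(rng.lognormal(np.log(1.8e5), 0.7)),
                    deamination=deam,
                    meth_level=meth,
                    expr_rpm=float(rng.uniform(0.2, 5.0)) if silenced
                    else float(rng.uniform(5.0, 60.0)),
                    silenced=silenced,
                    coding_capable=bool(rng.random() < 0.6),
                )
            )
    return plans


def _place_genes(cfg: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    gid = 0
    for ci in range(cfg.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_genes = max(2, cfg.chrom_length // 25_000)
        placed: list[tuple[int, int]] = []
        tries = 0
        while len(placed) < n_genes and tries < 50 * n_genes:
            tries += 1
            length = int(rng.integers(1000, 4000))
            start = int(rng.integers(0, cfg.chrom_length - length))
            if any(s < start + length and start < e for s, e in placed):
                continue
            placed.append((start, start + length))
            gid += 1
            rows.append(
                {
                    "gene_id": f"gene{gid:04d}",
                    "chrom": chrom,
                    "start": start,
                    "end": start + length,
                    "strand": "+" if rng.random() < 0.5 else "-",
                    # conserved at a syntenic position in the outgroup genome
                    "syntenic": bool(rng.random() < 0.6),
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["chrom", "start", "gene_id"])
        .reset_index(drop=True)
    )


def generate_dataset(config: SimConfig | None = None) -> SyntheticDataset:
    """Generate the complete self-consistent toy dataset.

    Copies arrive oldest-first; a nested insertion overwrites the host's
    bases at its location (annotated host span still includes them), so
    painting order matches the arrival order downstream nesting resolution
    reconstructs.  True ages drive sequence divergence, LTR-pair divergence
    (expected 2*mu*age) and terminal branch lengths (mu*age exactly).
    """
    cfg = config or SimConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]

    plans = _plan_families(cfg, rng)
    total_bp = sum(p.length * p.size for p in plans)
    genome_bp = cfg.n_chromosomes * cfg.chrom_length
    if total_bp > 0.6 * genome_bp:
        raise CapacityError(
            f"requested {total_bp} TE bp exceeds 60% of the {genome_bp} bp genome"
        )

    genes = _place_genes(cfg, rng)

    # --- draw copies with ages; arrival order = age descending ------------
    plan_of: dict[str, _FamilyPlan] = {}
    proto: list[tuple[str, str, float]] = []  # (copy_id, family, age)
    counter = 0
    for p in plans:
        plan_of[p.family_id] = p
        ages = rng.gamma(shape=1.5, scale=p.mean_age / 1.5, size=p.size)
        ages = np.clip(ages, 0.0, 1.2e6)
        for a in ages:
            counter += 1
            proto.append((f"te{counter:05d}", p.family_id, float(a)))
    proto.sort(key=lambda t: -t[2])

    # --- placement --------------------------------------------------------
    occupied: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    placed: dict[str, TECopy] = {}
    arrival: list[str] = []
    true_ages: dict[str, float] = {}

    def free_place(length: int) -> tuple[str, int] | None:
        for _ in range(300):
            chrom = chroms[int(rng.integers(len(chroms)))]
            start = int(rng.integers(0, cfg.chrom_length - length))
            end = start + length
            if all(e <= start or end <= s for s, e, _ in occupied[chrom]):
                return chrom, start
        return None

    def ancestors_of(cid: str) -> set[str]:
        out = set()
        cur = placed[cid].parent_te
        while cur is not None:
            out.add(cur)
            cur = placed[cur].parent_te
        return out

    def nested_place(length: int, age: float) -> tuple[str, int, str] | None:
        # the interrupted element must be older than the interrupter
        hosts = [
            c for c in placed.values()
            if c.span_bp >= length + 2 and true_ages[c.copy_id] > age
        ]
        if not hosts:
            return None
        for _ in range(60):
            host = hosts[int(rng.integers(len(hosts)))]
            start = int(rng.integers(host.start + 1, host.end - length))
            end = start + length
            # must not touch any other placed interval, except the chosen
            # host and its ancestors (which necessarily contain the child)
            allowed = {host.copy_id} | ancestors_of(host.copy_id)
            clash = any(
                s < end and start < e
                for s, e, cid in occupied[host.chrom]
                if cid not in allowed
            )
            if not clash:
                return host.chrom, start, host.copy_id
        return None

    def commit(cid: str, fam: str, age: float, chrom: str, start: int,
               parent: str | None) -> None:
        p = plan_of[fam]
        copy = TECopy(
            copy_id=cid, family_id=fam, superfamily=p.superfamily,
            chrom=chrom, start=start, end=start + p.length,
            strand="+" if rng.random() < 0.5 else "-", parent_te=parent,
        )
        placed[cid] = copy
        occupied[chrom].append((copy.start, copy.end, cid))
        arrival.append(cid)
        true_ages[cid] = age

    queue = list(proto)
    # guarantee one nesting chain of depth >= 3 when nesting is on
    if cfg.nesting_probability > 0 and len(queue) >= 3:
        by_len = sorted(queue, key=lambda t: -plan_of[t[1]].length)
        chain: list[tuple[str, str, float]] = []
        for item in by_len:
            if not chain or plan_of[item[1]].length <= plan_of[chain[-1][1]].length - 60:
                chain.append(item)
            if len(chain) == 3:
                break
        if len(chain) == 3 and plan_of[chain[2][1]].length >= 80:
            chain_ages = sorted((t[2] for t in chain), reverse=True)
            for item in chain:
                queue.remove(item)
            parent = None
            prev: TECopy | None = None
            for (cid, fam, _), age in zip(chain, chain_ages):
                p = plan_of[fam]
                if prev is None:
                    loc = free_place(p.length)
                    if loc is None:
                        raise CapacityError("cannot place forced nesting chain")
                    commit(cid, fam, age, loc[0], loc[1], None)
                else:
                    start = int(rng.integers(prev.start + 1, prev.end - p.length))
                    commit(cid, fam, age, prev.chrom, start, prev.copy_id)
                prev = placed[cid]

    for cid, fam, age in queue:
        p = plan_of[fam]
        parent = None
        spot = None
        if placed and rng.random() < cfg.nesting_probability:
            nested = nested_place(p.length, age)
            if nested is not None:
                spot = (nested[0], nested[1])
                parent = nested[2]
        if spot is None:
            spot = free_place(p.length)
            if spot is None:
                raise CapacityError(
                    f"cannot place copy {cid} ({p.length} bp): genome too full"
                )
        commit(cid, fam, age, spot[0], spot[1], parent)

    # --- sequences: background then paint copies in arrival order ---------
    genome_arr = {
        c: np.frombuffer(_random_seq(rng, cfg.chrom_length).encode(), dtype="S1").copy()
        for c in chroms
    }
    copy_seq: dict[str, str] = {}
    for cid in arrival:
        c = placed[cid]
        p = plan_of[c.family_id]
        n_subs = int(rng.binomial(p.length, min(1.0, cfg.mu * true_ages[cid])))
        seq = _mutate(rng, p.consensus, n_subs)
        copy_seq[cid] = seq
        genome_arr[c.chrom][c.start : c.end] = np.frombuffer(seq.encode(), dtype="S1")
    genome = {c: arr.tobytes().decode() for c, arr in genome_arr.items()}

    # --- LTR alignment pairs (at-insertion sequences, pre-nesting) --------
    ltr_alignments = {
        cid: (copy_seq[cid][: plan_of[placed[cid].family_id].ltr_len],
              copy_seq[cid][-plan_of[placed[cid].family_id].ltr_len :])
        for cid in arrival
        if plan_of[placed[cid].family_id].ltr_len > 0
    }

    # --- per-superfamily trees: terminal branch = mu * age ----------------
    trees = {}
    for sf in sorted(SUPERFAMILIES):
        ids = [cid for cid in arrival if placed[cid].superfamily == sf]
        if ids:
            ids = sorted(ids)
            trees[sf] = _star_newick(ids, [cfg.mu * true_ages[i] for i in ids])

    # --- methylation windows ----------------------------------------------
    fam_at: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}
    for cid in arrival:
        c = placed[cid]
        fam_at[c.chrom].append((c.start, c.end, c.family_id))
    meth_rows = []
    for chrom in chroms:
        seq = genome[chrom]
        spans = sorted(fam_at[chrom])
        for w in range(0, cfg.chrom_length, 100):
            mid = w + 50
            # innermost (latest-start) TE span covering the window midpoint
            covering = [sp for sp in spans if sp[0] <= mid < sp[1]]
            fam = max(covering)[2] if covering else None
            win = seq[w : w + 100]
            total_c = win.count("C") + win.count("G")
            for context in ("CG", "CHG", "CHH"):
                base_level = (
                    plan_of[fam].meth_level[context]
                    if fam is not None
                    else {"CG": 0.08, "CHG": 0.05, "CHH": 0.02}[context]
                )
                for tissue in cfg.tissue_names:
                    if rng.random() < 0.05:  # uncovered window -> missing later
                        continue
                    level = float(np.clip(base_level * rng.uniform(0.85, 1.15), 0, 1))
                    tc = max(0, int(total_c * {"CG": 0.2, "CHG": 0.3, "CHH": 0.5}[context]))
                    mc = int(rng.binomial(tc, level)) if tc else 0
                    meth_rows.append(
                        (chrom, w, context, tissue, mc, tc,
                         mc / tc if tc else np.nan)
                    )
    methylation = pd.DataFrame(
        meth_rows,
        columns=["chrom", "win_start", "context", "tissue",
                 "methylated_c", "total_c", "fraction"],
    )

    # --- expression --------------------------------------------------------
    lib_rows, cnt_rows = [], []
    fam_ids = sorted({p.family_id for p in plans})
    for tissue in cfg.tissue_names:
        for rep in (1, 2, 3):
            lib = int(rng.normal(1.0e6, 5.0e4))
            lib_rows.append({"tissue": tissue, "replicate": rep, "library_size": lib})
            for fam in fam_ids:
                p = plan_of[fam]
                # one or two tissues dominate for silenced/tissue-specific fams
                mult = 1.0
                if p.silenced and tissue != cfg.tissue_names[0]:
                    mult = 0.1
                lam = p.expr_rpm * mult * lib / 1e6
                cnt_rows.append(
                    {
                        "entity_id": fam,
                        "tissue": tissue,
                        "replicate": rep,
                        "count": int(rng.negative_binomial(5, 5 / (5 + lam)))
                        if lam > 0
                        else 0,
                    }
                )
    library_sizes = pd.DataFrame(lib_rows)
    te_counts = pd.DataFrame(cnt_rows)

    gene_rows = []
    for _, g in genes.iterrows():
        base = float(rng.lognormal(2.0, 1.0))
        specific = rng.random() < 0.3
        hot = int(rng.integers(len(cfg.tissue_names)))
        for ti, tissue in enumerate(cfg.tissue_names):
            val = base if (not specific or ti == hot) else base * 0.05
            gene_rows.append(
                {"entity_id": g.gene_id, "tissue": tissue,
                 "value": round(val * float(rng.uniform(0.8, 1.2)), 4)}
            )
    gene_expression = pd.DataFrame(gene_rows)

    # --- genetic map: smooth monotone cM ----------------------------------
    map_rows = []
    for chrom in chroms:
        pos = np.arange(0, cfg.chrom_length + 1, 5_000)
        incr = rng.gamma(2.0, 0.5, size=len(pos) - 1)
        cm = np.concatenate([[0.0], np.cumsum(incr)])
        cm *= (cfg.chrom_length / 1e6 * 1.5) / cm[-1]
        for p_, c_ in zip(pos, cm):
            map_rows.append({"chrom": chrom, "pos": int(p_), "cM": round(float(c_), 6)})
    genetic_map = pd.DataFrame(map_rows)

    # --- MNase hypersensitive intervals ------------------------------------
    mnase = {}
    for tissue in ("root", "shoot"):
        rows = []
        for chrom in chroms:
            n = cfg.chrom_length // 4000
            starts = np.sort(rng.integers(0, cfg.chrom_length - 400, size=n))
            for s in starts:
                rows.append(
                    {"chrom": chrom, "start": int(s),
                     "end": int(s + rng.integers(50, 400))}
                )
        mnase[tissue] = pd.DataFrame(rows)

    # --- variants -----------------------------------------------------------
    var_rows = []
    for chrom in chroms:
        n = int(cfg.chrom_length * 0.008)
        for p_ in np.sort(rng.choice(cfg.chrom_length, size=n, replace=False)):
            var_rows.append({"chrom": chrom, "pos": int(p_)})
    variants = pd.DataFrame(var_rows)

    # --- subgenome blocks ---------------------------------------------------
    sub_rows = []
    for chrom in chroms:
        block = cfg.chrom_length // 4
        label = "A" if rng.random() < 0.5 else "B"
        pos = 0
        while pos < cfg.chrom_length:
            end = min(pos + block, cfg.chrom_length)
            gap = int(rng.integers(0, block // 10))
            sub_rows.append(
                {"chrom": chrom, "start": pos, "end": max(pos + 1, end - gap),
                 "subgenome": label}
            )
            label = "B" if label == "A" else "A"
            pos = end
    subgenomes = pd.DataFrame(sub_rows)

    # --- protein-domain hits -----------------------------------------------
    dom_rows = []
    for cid in arrival:
        c = placed[cid]
        p = plan_of[c.family_id]
        if not p.coding_capable:
            continue
        p_intact = float(np.exp(-true_ages[cid] / 6.0e5))
        if c.superfamily in LTR_SUPERFAMILIES:
            if rng.random() < p_intact:
                doms = ["GAG", "AP", "RT", "RNaseH", "INT"]
            elif rng.random() < 0.4:
                doms = ["GAG"]
            elif rng.random() < 0.4:
                doms = ["AP", "RT", "RNaseH", "INT"]
            else:
                doms = []
        elif c.superfamily == "DHH":
            doms = ["RepHel"] if rng.random() < p_intact else []
        elif c.superfamily in ("RIL", "RIT"):
            doms = ["RT"] if rng.random() < p_intact else []
        elif c.superfamily == "RST":
            doms = []
        else:
            doms = ["TPase"] if rng.random() < p_intact else []
        for d in doms:
            dom_rows.append({"copy_id": cid, "domain": d})
    domain_hits = pd.DataFrame(dom_rows, columns=["copy_id", "domain"])

    family_truth = pd.DataFrame(
        [
            {
                "family_id": p.family_id,
                "superfamily": p.superfamily,
                "length": p.length,
                "size_drawn": p.size,
                "mean_age": p.mean_age,
                "deamination": p.deamination,
                "meth_cg": p.meth_level["CG"],
                "expr_rpm": p.expr_rpm,
                "silenced": p.silenced,
                "coding_capable": p.coding_capable,
            }
            for p in plans
        ]
    )

    return SyntheticDataset(
        config=cfg,
        te_copies=[placed[cid] for cid in arrival],
        genes=genes,
        genome=genome,
        true_ages=true_ages,
        arrival_order=arrival,
        trees=trees,
        ltr_alignments=ltr_alignments,
        methylation=methylation,
        te_counts=te_counts,
        library_sizes=library_sizes,
        gene_expression=gene_expression,
        genetic_map=genetic_map,
        mnase=mnase,
        variants=variants,
        subgenomes=subgenomes,
        domain_hits=domain_hits,
        family_truth=family_truth,
    )
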