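"""End-to-end orchestration: load input layers, run every stage in dependency
order (resolve -> ages -> features -> profiles -> expression -> model), and
write stamped artifacts to a run directory.

Stages are skipped on rerun when their stamp (a hash of the configuration)
matches and their outputs exist, so a rerun with an unchanged config is a
no-op and the emitted model report is byte-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from . import annotation, composition, context, expression, methylation
from .ages import MU_MAIZE, ltr_pair_ages, read_ltr_alignments, terminal_branch_ages
from .model import TEAgeModel, assemble_features

log = logging.getLogger("te_ecology")

__all__ = ["PipelineConfig", "run_pipeline", "load_layers"]


@dataclass
class PipelineConfig:
    """All knobs of the analysis, with the study defaults.

    ``flank_bp`` (1 kb) applies to composition/chromatin/diversity flanks;
    methylation profiles use 20 x 100 bp flanking windows per side.
    """

    input_dir: str = "."
    output_dir: str = "run"
    mu: float = MU_MAIZE
    window_bp: int = 100
    flank_bp: int = 1000
    n_flank_windows: int = 20
    min_surviving_bp: int = 50
    min_copies_for_reporting: int = 10
    seed: int = 0
    n_trees: int = 1000
    train_frac: float = 0.5
    importance_repeats: int = 20
    ice_features: tuple[str, ...] = ()

    def validate(self) -> None:
        for name in ("mu", "window_bp", "flank_bp", "min_surviving_bp", "n_trees"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.train_frac < 1):
            raise ValueError("train_frac must lie in (0, 1)")

    def config_hash(self) -> str:
        # paths excluded: the hash identifies the analysis, not its location
        d = dataclasses.asdict(self)
        d.pop("input_dir")
        d.pop("output_dir")
        d["ice_features"] = list(d["ice_features"])
        return hashlib.sha256(
            json.dumps(d, sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ice_features" in data:
            data["ice_features"] = tuple(data["ice_features"])
        return cls(**data)


@dataclass
class Layers:
    """In-memory input layers of one run."""

    te_copies: list
    genes: pd.DataFrame
    genome: dict[str, str]
    trees: dict[str, str]
    ltr_alignments: dict
    methylation: pd.DataFrame
    te_counts: pd.DataFrame
    library_sizes: pd.DataFrame
    gene_expression: pd.DataFrame
    genetic_map: pd.DataFrame
    mnase: dict[str, pd.DataFrame]
    variants: pd.DataFrame
    subgenomes: pd.DataFrame
    domain_hits: pd.DataFrame
    syntenic_ids: set[str] | None = None
    missing: list[str] = field(default_factory=list)


def _maybe(path: Path, loader, default, missing: list[str]):
    if path.exists():
        return loader(path)
    missing.append(path.name)
    return default


def load_layers(input_dir: str | Path) -> Layers:
    """Load every input layer found under ``input_dir``; absent optional
    layers are recorded and their features later coded missing."""
    d = Path(input_dir)
    missing: list[str] = []
    te = annotation.read_te_gff(d / "te.gff3")
    genome = {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(d / "genome.fa"), "fasta")
    }
    trees = {}
    treedir = d / "trees"
    if treedir.is_dir():
        for f in sorted(treedir.glob("*.nwk")):
            trees[f.stem] = f.read_text().strip()
    else:
        missing.append("trees/")
    read_tsv = lambda p: pd.read_csv(p, sep="\t")
    empty = pd.DataFrame()
    return Layers(
        te_copies=te,
        genes=_maybe(d / "genes.gff3", annotation.read_gene_gff, empty, missing),
        genome=genome,
        trees=trees,
        ltr_alignments=_maybe(
            d / "ltr_alignments.fasta", read_ltr_alignments, {}, missing
        ),
        methylation=_maybe(d / "methylation_windows.tsv", read_tsv, empty, missing),
        te_counts=_maybe(d / "te_counts.tsv", read_tsv, empty, missing),
        library_sizes=_maybe(d / "library_sizes.tsv", read_tsv, empty, missing),
        gene_expression=_maybe(d / "gene_expression.tsv", read_tsv, empty, missing),
        genetic_map=_maybe(d / "genetic_map.tsv", read_tsv, empty, missing),
        mnase={
            f.stem.replace("mnase_", ""): pd.read_csv(
                f, sep="\t", names=["chrom", "start", "end"]
            )
            for f in sorted(d.glob("mnase_*.bed"))
        },
        variants=_maybe(d / "variants.tsv", read_tsv, empty, missing),
        subgenomes=_maybe(
            d / "subgenomes.bed",
            lambda p: pd.read_csv(
                p, sep="\t", names=["chrom", "start", "end", "subgenome"]
            ),
            empty,
            missing,
        ),
        domain_hits=_maybe(
            d / "domain_hits.tsv", read_tsv,
            pd.DataFrame(columns=["copy_id", "domain"]), missing,
        ),
        syntenic_ids=_maybe(
            d / "syntenic_genes.txt",
            lambda p: {line.strip() for line in p.read_text().splitlines() if line.strip()},
            None,
            missing,
        ),
    )


# --------------------------------------------------------------------------
# feature computation


def compute_copy_features(layers: Layers, resolved, cfg: PipelineConfig) -> dict[str, pd.DataFrame]:
    """Per-copy feature frames keyed by model category."""
    chrom_len = {c: len(s) for c, s in layers.genome.items()}
    kept = resolved.kept_ids()

    def seq_of(chrom, s, e):
        return layers.genome[chrom][s:e]

    # --- TE / flank base composition
    te_comp, flank_comp = [], []
    for cid in kept:
        c = resolved.copies[cid]
        segs = [seq_of(c.chrom, s, e) for s, e in resolved.segments[cid]]
        f = composition.composition_of_segments(segs, region_id=cid)
        te_comp.append(
            {"copy_id": cid, "gc_te": f.gc, "p_cg_te": f.p_cg, "p_chg_te": f.p_chg,
             "p_chh_te": f.p_chh, "p_tgca_te": f.p_tgca,
             "length_bp": resolved.surviving_bp[cid], "span_bp": resolved.span_bp[cid]}
        )
        left, right = composition.extract_flanks(
            seq_of, c.chrom, c.start, c.end, chrom_len[c.chrom], cfg.flank_bp
        )
        if left or right:
            g = composition.pooled_composition(left, right, region_id=cid)
            flank_comp.append(
                {"copy_id": cid, "gc_flank": g.gc, "p_cg_flank": g.p_cg,
                 "p_chg_flank": g.p_chg, "p_chh_flank": g.p_chh,
                 "p_tgca_flank": g.p_tgca}
            )
    te_comp = pd.DataFrame(te_comp).set_index("copy_id")
    flank_comp = pd.DataFrame(flank_comp).set_index("copy_id")

    # --- regional context
    maps = {}
    if not layers.genetic_map.empty:
        for chrom, grp in layers.genetic_map.groupby("chrom"):
            maps[chrom] = context.fit_monotonic_map(grp)
    var_pos = {
        chrom: np.sort(grp["pos"].to_numpy())
        for chrom, grp in (layers.variants.groupby("chrom") if not layers.variants.empty else [])
    }
    ctx_rows = []
    for cid in kept:
        c = resolved.copies[cid]
        row = {"copy_id": cid}
        if not layers.genes.empty:
            row.update(
                context.nearest_gene_features(
                    (c.chrom, c.start, c.end), layers.genes,
                    syntenic_ids=layers.syntenic_ids,
                )
            )
        if c.chrom in maps:
            rate, extr = context.te_recombination_rate((c.start, c.end), maps[c.chrom])
            row["cm_mb"] = rate
        flanks = [
            (max(0, c.start - cfg.flank_bp), c.start),
            (c.end, min(chrom_len[c.chrom], c.end + cfg.flank_bp)),
        ]
        for tissue, hs in layers.mnase.items():
            sub = hs[hs["chrom"] == c.chrom]
            m = context.mnase_features((c.start, c.end), flanks, sub)
            row.update({f"{k}_{tissue}": v for k, v in m.items()})
        if c.chrom in var_pos:
            row["segsites_per_bp_te"] = context.segregating_site_density(
                (c.start, c.end), var_pos[c.chrom]
            )
            fl_bp = sum(e - s for s, e in flanks if e > s)
            fl_sites = sum(
                context.segregating_site_density((s, e), var_pos[c.chrom]) * (e - s)
                for s, e in flanks
                if e > s
            )
            row["segsites_per_bp_flank"] = fl_sites / fl_bp if fl_bp else np.nan
        if not layers.subgenomes.empty:
            sub = layers.subgenomes[layers.subgenomes["chrom"] == c.chrom]
            sg = context.subgenome_assign((c.start, c.end), sub)
            row["subgenome_A"] = {"A": 1.0, "B": 0.0}.get(sg, np.nan)
        ctx_rows.append(row)
    ctx = pd.DataFrame(ctx_rows).set_index("copy_id")
    ctx = ctx.drop(columns=[c for c in ("closest_gene_id", "closest_syntenic_gene_id")
                            if c in ctx.columns])
    if "within_transcript" in ctx.columns:
        ctx["within_transcript"] = ctx["within_transcript"].astype(float)

    regional_sel = [c for c in ("dist_gene", "dist_syntenic_gene", "within_transcript",
                                "cm_mb", "segsites_per_bp_te", "segsites_per_bp_flank",
                                "subgenome_A") if c in ctx.columns]
    mnase_te = [c for c in ctx.columns if c.startswith(("mnase_count_te", "mnase_prop_te"))]
    mnase_flank = [c for c in ctx.columns
                   if c.startswith(("mnase_count_flank", "mnase_prop_flank"))]

    frames: dict[str, pd.DataFrame] = {
        "TE base composition": te_comp,
        "regional base composition": flank_comp,
        "regional recombination and selection": ctx[regional_sel],
    }

    # --- methylation profiles (body -> TE category, flanks -> regional)
    if not layers.methylation.empty:
        wins = layers.methylation.rename(columns={"win_start": "win_start"})
        wide_body, wide_flank = _methylation_features(resolved, wins, chrom_len)
        frames["TE methylation and chromatin accessibility"] = pd.concat(
            [wide_body, ctx[mnase_te]], axis=1
        )
        frames["regional methylation and chromatin accessibility"] = pd.concat(
            [wide_flank, ctx[mnase_flank]], axis=1
        )
    else:
        frames["TE methylation and chromatin accessibility"] = ctx[mnase_te]
        frames["regional methylation and chromatin accessibility"] = ctx[mnase_flank]

    return frames


def _methylation_features(resolved, windows: pd.DataFrame, chrom_len) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Wide per-copy methylation features from imputed 41-slot profiles:
    body mean per (tissue, context), plus mean over each side's 20 flank
    windows per (tissue, context)."""
    prof = methylation.profile_table(resolved, windows, chrom_len)
    fam_of = {cid: resolved.copies[cid].family_id for cid in resolved.copies}
    sf_of = {cid: resolved.copies[cid].superfamily for cid in resolved.copies}
    imputed = methylation.impute_missing(prof, fam_of, sf_of)
    body = imputed[imputed["slot"] == 0]
    wide_body = body.pivot_table(
        index="copy_id", columns=["context", "tissue"], values="value"
    )
    wide_body.columns = [f"meth_{c}_{t}_te" for c, t in wide_body.columns]
    flank = imputed[imputed["slot"] != 0]
    wide_flank = flank.pivot_table(
        index="copy_id", columns=["context", "tissue"], values="value"
    )
    wide_flank.columns = [f"meth_{c}_{t}_flank" for c, t in wide_flank.columns]
    return wide_body, wide_flank


def expression_features(
    layers: Layers,
    resolved,
    ctx_gene_ids: pd.Series | None = None,
    ctx_syntenic_ids: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """TE-family expression (per-copy RPM median + tau) mapped onto copies,
    and nearest-gene expression summaries."""
    frames: dict[str, pd.DataFrame] = {}
    kept = resolved.kept_ids()
    fam_of = pd.Series({cid: resolved.copies[cid].family_id for cid in kept})
    if not layers.te_counts.empty and not layers.library_sizes.empty:
        fam_sizes = fam_of.value_counts()
        rpm = expression.per_copy_family_rpm(
            layers.te_counts[layers.te_counts["entity_id"].isin(fam_sizes.index)],
            layers.library_sizes,
            fam_sizes,
        )
        summ = expression.expression_summary_table(rpm, "per_copy_rpm").set_index("entity_id")
        te_expr = pd.DataFrame(
            {
                "te_family_median_rpm": fam_of.map(summ["median_expr"]),
                "te_family_tau": fam_of.map(summ["tau"]),
            }
        )
        frames["TE expression"] = te_expr
    if not layers.gene_expression.empty and ctx_gene_ids is not None:
        gsum = expression.expression_summary_table(
            layers.gene_expression, "value"
        ).set_index("entity_id")
        cols = {
            "closest_gene_median_expr": ctx_gene_ids.map(gsum["median_expr"]),
            "closest_gene_tau": ctx_gene_ids.map(gsum["tau"]),
        }
        if ctx_syntenic_ids is not None:
            cols["closest_syntenic_gene_median_expr"] = ctx_syntenic_ids.map(
                gsum["median_expr"]
            )
            cols["closest_syntenic_gene_tau"] = ctx_syntenic_ids.map(gsum["tau"])
        frames["nearest gene expression"] = pd.DataFrame(cols)
    return frames


def protein_features(layers: Layers, copies, resolved) -> pd.DataFrame:
    calls = annotation.classify_autonomy(copies, layers.domain_hits, resolved)
    df = annotation.autonomy_frame(calls).set_index("copy_id")
    return pd.DataFrame(
        {
            "autonomous_coding": (df["status"] == "autonomous_coding").astype(float),
            "partial_coding": (df["status"] == "partial_coding").astype(float),
            "family_has_coding_member": df["family_has_coding_member"].astype(float),
        }
    )


# --------------------------------------------------------------------------
# stage runner


def _stamp_ok(outdir: Path, stage: str, h: str, outputs: list[Path]) -> bool:
    stamp = outdir / f".{stage}.stamp"
    return stamp.exists() and stamp.read_text() == h and all(p.exists() for p in outputs)


def _write_stamp(outdir: Path, stage: str, h: str) -> None:
    (outdir / f".{stage}.stamp").write_text(h)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run all stages; returns the run directory.

    Every artifact is stamped with the configuration hash; stages whose
    stamp is current are skipped on rerun.
    """
    cfg.validate()
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    h = cfg.config_hash()
    log.info("run %s (config hash %s)", out, h)
    layers = load_layers(cfg.input_dir)
    for m in layers.missing:
        log.warning("input layer %s missing; downstream features coded -1", m)

    # resolve ----------------------------------------------------------------
    resolved = annotation.resolve_nesting(layers.te_copies, cfg.min_surviving_bp)
    if not _stamp_ok(out, "resolve", h, [out / "resolved_copies.tsv"]):
        resolved.to_frame().to_csv(out / "resolved_copies.tsv", sep="\t", index=False)
        resolved.segments_frame().to_csv(out / "segments.tsv", sep="\t", index=False)
        _write_stamp(out, "resolve", h)

    # ages -------------------------------------------------------------------
    tbl_ages: dict[str, float] = {}
    for sf, newick in layers.trees.items():
        for est in terminal_branch_ages(newick, cfg.mu):
            tbl_ages[est.copy_id] = est.age_years
    divs, ltr_ages_list, saturated = ltr_pair_ages(layers.ltr_alignments, cfg.mu)
    if saturated:
        log.warning("%d LTR pairs saturated; excluded", len(saturated))
    age_rows = [
        {"copy_id": cid, "method": "terminal_branch", "P": np.nan, "Q": np.nan,
         "d": a * cfg.mu, "age_years": a}
        for cid, a in sorted(tbl_ages.items())
    ]
    ltr_age_map = {a.copy_id: a.age_years for a in ltr_ages_list}
    for dv in divs:
        age_rows.append(
            {"copy_id": dv.copy_id, "method": "ltr_ltr", "P": dv.P, "Q": dv.Q,
             "d": dv.d, "age_years": ltr_age_map[dv.copy_id]}
        )
    ages_df = pd.DataFrame(age_rows)
    if not _stamp_ok(out, "ages", h, [out / "ages.tsv"]):
        ages_df.to_csv(out / "ages.tsv", sep="\t", index=False, float_format="%.8g")
        _write_stamp(out, "ages", h)

    kept = resolved.kept_ids()
    ages = pd.Series({cid: tbl_ages.get(cid, np.nan) for cid in kept}).dropna()

    # features ---------------------------------------------------------------
    frames = compute_copy_features(layers, resolved, cfg)
    # nearest-gene ids for gene-expression mapping
    gene_ids, syn_ids = {}, {}
    if not layers.genes.empty:
        for cid in kept:
            c = resolved.copies[cid]
            nf = context.nearest_gene_features(
                (c.chrom, c.start, c.end), layers.genes,
                syntenic_ids=layers.syntenic_ids,
            )
            gene_ids[cid] = nf["closest_gene_id"]
            syn_ids[cid] = nf.get("closest_syntenic_gene_id")
    frames.update(
        expression_features(
            layers, resolved, pd.Series(gene_ids),
            pd.Series(syn_ids) if layers.syntenic_ids is not None else None,
        )
    )
    frames["TE-encoded proteins"] = protein_features(layers, layers.te_copies, resolved)

    sf = pd.Series({cid: resolved.copies[cid].superfamily for cid in kept})
    fam = pd.Series({cid: resolved.copies[cid].family_id for cid in kept})
    model_ids = [cid for cid in kept if cid in ages.index]
    table = assemble_features(frames, sf, fam, copy_ids=model_ids)
    if not _stamp_ok(out, "features", h, [out / "feature_table.tsv"]):
        table.X.rename_axis("copy_id").to_csv(
            out / "feature_table.tsv", sep="\t", float_format="%.8g"
        )
        pd.Series(table.category_map, name="category").rename_axis("feature").to_csv(
            out / "category_manifest.tsv", sep="\t"
        )
        _write_stamp(out, "features", h)

    # family summary ----------------------------------------------------------
    calls = annotation.classify_autonomy(layers.te_copies, layers.domain_hits, resolved)
    fam_summary = annotation.family_summary(
        resolved, ages.reindex(kept).fillna(ages.median()),
        autonomy=calls, min_copies_for_reporting=cfg.min_copies_for_reporting,
    )
    if not _stamp_ok(out, "family_summary", h, [out / "family_summary.tsv"]):
        fam_summary.to_csv(out / "family_summary.tsv", sep="\t", index=False,
                           float_format="%.8g")
        _write_stamp(out, "family_summary", h)

    # model -------------------------------------------------------------------
    model_outputs = [out / "model_report.json", out / "importance.tsv"]
    if not _stamp_ok(out, "model", h, model_outputs):
        model = TEAgeModel(table, ages.loc[model_ids])
        res = model.fit(seed=cfg.seed, n_trees=cfg.n_trees, train_frac=cfg.train_frac)
        feat_imp, cat_imp = res.permutation_importance(n_repeats=cfg.importance_repeats)
        feat_imp.to_csv(out / "importance.tsv", sep="\t", index=False,
                        float_format="%.8g")
        cat_imp.to_csv(out / "category_importance.tsv", sep="\t", index=False,
                       float_format="%.8g")
        corr = res.family_feature_correlations()
        corr.rename_axis("feature").to_csv(out / "family_correlations.tsv", sep="\t",
                                           float_format="%.6g")
        report = res.to_report()
        report["config_hash"] = h
        report["top_features"] = feat_imp["feature"].head(10).tolist()
        for feat_name in cfg.ice_features:
            ice = res.ice_curves(feat_name)
            ice.superfamily_means.rename_axis("superfamily").to_csv(
                out / f"ice_{feat_name}.tsv", sep="\t", float_format="%.8g"
            )
        (out / "model_report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n"
        )
        _write_stamp(out, "model", h)
    return out
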