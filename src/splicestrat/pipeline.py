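"""Pipeline orchestration: quantify -> stratify -> diffexp -> survival ->
protein -> variants, per cancer type, with tidy CSV outputs.

Each stage reads its inputs from files on disk and writes its outputs
before the next stage starts, so running :func:`run_all` is equivalent to
running the individual stage functions (or CLI subcommands) in sequence on
the same directory.  A failure inside one cancer type is logged into the
run report and skipped rather than aborting the whole run, mirroring how a
pan-cancer analysis drops cohorts lacking normal tissue.

Every output CSV starts with a provenance comment line
(``# splicestrat <version> config_hash=... seed=...``); report bodies
exclude timestamps and absolute paths so identical configs reproduce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, SpliceStratError, UsageError
from .groupstats import adjust_bh, oneway_anova, protein_by_group, wilcoxon_rank_sum
from .junctions import (
    IsoformDefinition,
    default_isoform_definitions,
    parse_junction_region,
    quantify_isoforms,
    read_expression_csv,
    read_junction_matrix,
    write_expression_csv,
)
from .stratify import GroupLabel, map_race, split_by_mean, split_zero_nonzero
from .survival import (
    collapse_stage,
    cox_fit,
    forest_table,
    km_estimate,
    logrank_test,
    make_design,
)
from .variants import default_pik3r1_regions, read_variants, tally_consequences

logger = logging.getLogger("splicestrat")

__all__ = ["PipelineConfig", "run_all", "stage_quantify", "stage_stratify",
           "stage_diffexp", "stage_survival", "stage_protein", "stage_variants"]


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run."""

    junction_path: str
    clinical_path: str
    protein_path: str | None = None
    variant_path: str | None = None
    junction_format: str = "tsv"  # tsv | star_sj
    variant_format: str = "tsv"  # tsv | vcf
    # isoform definitions: name -> junction string; None = PIK3R1 defaults
    isoforms: dict[str, str] | None = None
    gene: str = "PIK3R1"
    pseudocount: float = 1.0
    mean_split_isoform: str = "p85a"
    zero_split_isoform: str = "p55a"
    exact_wilcoxon_limit: int = 12
    bh_correction: bool = False
    ties: str = "efron"
    endpoints: tuple[str, ...] = ("OS", "PFI")
    seed: int = 0

    def definitions(self) -> list[IsoformDefinition]:
        if self.isoforms is None:
            return default_isoform_definitions()
        return [
            IsoformDefinition(name, self.gene, (parse_junction_region(s),))
            for name, s in self.isoforms.items()
        ]

    def validate(self) -> None:
        for name, path in (("junction_path", self.junction_path),
                           ("clinical_path", self.clinical_path),
                           ("protein_path", self.protein_path),
                           ("variant_path", self.variant_path)):
            if path is not None and not Path(path).exists():
                raise ConfigError(f"PipelineConfig.{name}: no such file {path!r}")
        names = [d.name for d in self.definitions()]
        for attr in ("mean_split_isoform", "zero_split_isoform"):
            if getattr(self, attr) not in names:
                raise ConfigError(
                    f"PipelineConfig.{attr}: {getattr(self, attr)!r} is not a "
                    f"defined isoform (have {names})"
                )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of PipelineConfig fields")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown fields {sorted(unknown)}")
        if "endpoints" in data:
            data["endpoints"] = tuple(data["endpoints"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        data = dataclasses.asdict(self)
        # hash options, not machine-specific absolute paths
        for key in ("junction_path", "clinical_path", "protein_path", "variant_path"):
            data[key] = Path(data[key]).name if data[key] else None
        payload = yaml.safe_dump(data, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _write_csv(df: pd.DataFrame, path: Path, cfg: PipelineConfig, index=False) -> None:
    with open(path, "w") as fh:
        fh.write(f"# splicestrat {__version__} config_hash={cfg.config_hash()} "
                 f"seed={cfg.seed}\n")
        df.to_csv(fh, index=index, float_format="%.12g")


def _load_clinical(cfg: PipelineConfig) -> pd.DataFrame:
    clin = pd.read_csv(cfg.clinical_path, comment="#")
    required = {"bcr_patient_barcode", "type", "sample_type"}
    missing = required - set(clin.columns)
    if missing:
        raise ConfigError(
            f"clinical table missing required columns: {sorted(missing)}"
        )
    clin = clin.set_index(clin["bcr_patient_barcode"].astype(str), drop=False)
    clin["race_group"] = clin.get("race", pd.Series(index=clin.index)).map(map_race)
    return clin


# ------------------------------------------------------------------- stages


def stage_quantify(cfg: PipelineConfig, outdir: Path) -> Path:
    """Junction matrix + isoform definitions -> expression.csv."""
    jm = read_junction_matrix(cfg.junction_path, format=cfg.junction_format)
    clin = _load_clinical(cfg)
    et = quantify_isoforms(
        jm, cfg.definitions(), pseudocount=cfg.pseudocount,
        sample_type=clin["sample_type"],
    )
    path = outdir / "expression.csv"
    # write with provenance header, then the table
    with open(path, "w") as fh:
        fh.write(f"# splicestrat {__version__} config_hash={cfg.config_hash()} "
                 f"seed={cfg.seed}\n")
        et.to_frame().to_csv(fh, float_format="%.15g")
    return path


def _expression_with_clinical(cfg: PipelineConfig, outdir: Path):
    et = read_expression_csv(outdir / "expression.csv", pseudocount=cfg.pseudocount)
    clin = _load_clinical(cfg)
    frame = et.to_frame().join(clin[["type", "race_group"]], how="left")
    missing = frame["type"].isna()
    if missing.any():
        raise ConfigError(
            f"{int(missing.sum())} expression barcodes absent from clinical table"
        )
    return et, clin, frame


def stage_stratify(cfg: PipelineConfig, outdir: Path) -> Path:
    """Per-cancer tumor group labels for both stratification rules."""
    et, clin, frame = _expression_with_clinical(cfg, outdir)
    rows = []
    for cancer, sub in frame.groupby("type", sort=True):
        tumors = sub[sub["sample_type"] == "tumor"]
        if len(tumors) >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", UserWarning)
                labels = split_by_mean(tumors[f"{cfg.mean_split_isoform}_log"])
            for gl in labels:
                rows.append({"barcode": gl.barcode, "cancer": cancer,
                             "isoform": cfg.mean_split_isoform, "rule": gl.rule,
                             "label": gl.label, "threshold": gl.threshold_used})
        for gl in split_zero_nonzero(tumors[f"{cfg.zero_split_isoform}_raw"]):
            rows.append({"barcode": gl.barcode, "cancer": cancer,
                         "isoform": cfg.zero_split_isoform, "rule": gl.rule,
                         "label": gl.label, "threshold": gl.threshold_used})
    path = outdir / "groups.csv"
    _write_csv(pd.DataFrame(rows), path, cfg)
    return path


def stage_diffexp(cfg: PipelineConfig, outdir: Path) -> Path:
    """Tumor-vs-normal Wilcoxon and race-stratified ANOVA per cancer/isoform."""
    et, clin, frame = _expression_with_clinical(cfg, outdir)
    wilcox_rows, anova_rows = [], []
    for cancer, sub in frame.groupby("type", sort=True):
        tumors = sub[sub["sample_type"] == "tumor"]
        normals = sub[sub["sample_type"] == "normal"]
        for iso in et.isoforms:
            col = f"{iso}_log"
            if len(tumors) == 0 or len(normals) == 0:
                logger.info("diffexp skipped for %s/%s: missing a sample type",
                            cancer, iso)
                continue
            res = wilcoxon_rank_sum(
                tumors[col].to_numpy(), normals[col].to_numpy(),
                mode="auto", exact_limit=cfg.exact_wilcoxon_limit,
            )
            expected_w = len(tumors) * (len(tumors) + len(normals) + 1) / 2.0
            direction = ("tumor_up" if res.statistic > expected_w
                         else "tumor_down" if res.statistic < expected_w else "none")
            wilcox_rows.append({
                "cancer": cancer, "isoform": iso,
                "n_tumor": len(tumors), "n_normal": len(normals),
                "statistic": res.statistic, "p_value": res.p_value,
                "method": res.method, "direction": direction,
            })
            groups, names = [], []
            for label, grp in (("normal", normals),
                               ("tumor_AA", tumors[tumors["race_group"] == "AA"]),
                               ("tumor_EA", tumors[tumors["race_group"] == "EA"])):
                if len(grp) >= 2:
                    groups.append(grp[col].to_numpy())
                    names.append(label)
            if len(groups) >= 2:
                ares = oneway_anova(groups)
                anova_rows.append({
                    "cancer": cancer, "isoform": iso,
                    "groups": "|".join(names),
                    "n_per_group": "|".join(str(n) for n in ares.n_per_group),
                    "F": ares.statistic, "p_value": ares.p_value,
                })
    wdf = pd.DataFrame(wilcox_rows)
    if cfg.bh_correction and len(wdf):
        wdf["p_adjusted"] = adjust_bh(wdf["p_value"])
    path = outdir / "diffexp.csv"
    _write_csv(wdf, path, cfg)
    _write_csv(pd.DataFrame(anova_rows), outdir / "race_anova.csv", cfg)
    return path


_COX_CATEGORICALS = {
    "group": "high",
    "gender": None,
    "race_group": "EA",
    "stage_band": "early",
    "smoking_history": "NO",
    "alcohol_history": "NO",
}


def stage_survival(cfg: PipelineConfig, outdir: Path) -> Path:
    """Log-rank and multivariate Cox per cancer, isoform rule, and endpoint."""
    et, clin, frame = _expression_with_clinical(cfg, outdir)
    groups = pd.read_csv(outdir / "groups.csv", comment="#")
    logrank_rows, cox_rows = [], []
    for (cancer, iso), sub in groups.groupby(["cancer", "isoform"], sort=True):
        labels = sub.set_index("barcode")["label"]
        meta = clin.loc[clin.index.intersection(labels.index)].copy()
        meta["group"] = labels
        for endpoint in cfg.endpoints:
            tcol, ecol = f"{endpoint}_time", f"{endpoint}_event"
            if tcol not in meta or ecol not in meta:
                raise ConfigError(
                    f"clinical table lacks {tcol}/{ecol} for endpoint {endpoint}"
                )
            surv = meta.dropna(subset=[tcol, ecol, "group"])
            if surv["group"].nunique() < 2 or surv[ecol].sum() < 1:
                logger.info("log-rank skipped for %s/%s/%s: degenerate groups",
                            cancer, iso, endpoint)
                continue
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    lr = logrank_test(surv[tcol], surv[ecol], surv["group"])
                logrank_rows.append({
                    "cancer": cancer, "isoform": iso, "endpoint": endpoint,
                    "n": len(surv), "n_events": int(surv[ecol].sum()),
                    "chi2": lr.statistic, "df": lr.df, "p_value": lr.p_value,
                })
            except SpliceStratError as exc:
                logger.warning("log-rank failed for %s/%s/%s: %s",
                               cancer, iso, endpoint, exc)
                continue
            # multivariate Cox adjusting for age, sex, race, stage,
            # smoking and alcohol history (AA/EA rows only)
            model = surv[surv["race_group"].isin(["AA", "EA"])].copy()
            model["stage_band"] = collapse_stage(model.get("ajcc_stage",
                                                           pd.Series(index=model.index)))
            try:
                design = make_design(
                    model.assign(**{tcol: model[tcol], ecol: model[ecol]}),
                    continuous=["age"],
                    categorical=_COX_CATEGORICALS,
                )
                kept = model.loc[design.index]
                fit = cox_fit(kept[tcol], kept[ecol], design, ties=cfg.ties)
                tab = forest_table(fit)
                for rec in tab.itertuples(index=False):
                    cox_rows.append({
                        "cancer": cancer, "isoform": iso, "endpoint": endpoint,
                        "n": fit.n, "n_events": fit.n_events,
                        "covariate": rec.covariate, "hr": rec.hr,
                        "ci_low": rec.ci_low, "ci_high": rec.ci_high,
                        "p_value": rec.p, "stars": rec.stars,
                        "n_dropped_missing": len(model) - fit.n,
                    })
            except SpliceStratError as exc:
                logger.warning("Cox skipped for %s/%s/%s: %s",
                               cancer, iso, endpoint, exc)
    path = outdir / "logrank.csv"
    _write_csv(pd.DataFrame(logrank_rows), path, cfg)
    _write_csv(pd.DataFrame(cox_rows), outdir / "cox.csv", cfg)
    return path


def stage_protein(cfg: PipelineConfig, outdir: Path) -> Path | None:
    """Protein-by-isoform-group comparisons; None when no protein table."""
    if cfg.protein_path is None:
        return None
    et, clin, frame = _expression_with_clinical(cfg, outdir)
    protein = pd.read_csv(cfg.protein_path, index_col=0, comment="#")
    groups = pd.read_csv(outdir / "groups.csv", comment="#")
    zsub = groups[groups["isoform"] == cfg.zero_split_isoform]
    rows = []
    for cancer, sub in zsub.groupby("cancer", sort=True):
        labels = [GroupLabel(r.barcode, r.rule, r.label, r.threshold)
                  for r in sub.itertuples(index=False)]
        table = protein.loc[protein.index.intersection(sub["barcode"])]
        if table.empty:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = protein_by_group(table, labels)
        res.insert(0, "cancer", cancer)
        rows.append(res)
    out = (pd.concat(rows, ignore_index=True) if rows
           else pd.DataFrame(columns=["cancer", "protein", "n_low", "n_high",
                                      "statistic", "p_value"]))
    if cfg.bh_correction and len(out):
        out["p_adjusted"] = adjust_bh(out["p_value"])
    path = outdir / "protein_tests.csv"
    _write_csv(out, path, cfg)
    return path


def stage_variants(cfg: PipelineConfig, outdir: Path) -> Path | None:
    """Region/consequence tally of the variant table; None when absent."""
    if cfg.variant_path is None:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        records = read_variants(cfg.variant_path, format=cfg.variant_format)
        tally = tally_consequences(records, default_pik3r1_regions())
    path = outdir / "variant_tally.csv"
    with open(path, "w") as fh:
        fh.write(f"# splicestrat {__version__} config_hash={cfg.config_hash()} "
                 f"seed={cfg.seed}\n")
        out = tally.counts.copy()
        out.loc["total"] = tally.totals
        out.index.name = "consequence_class"
        out.to_csv(fh)
    shared = pd.DataFrame({"shared_rsid": tally.shared_rsids})
    _write_csv(shared, outdir / "shared_variants.csv", cfg)
    return path


# ------------------------------------------------------------------ run_all


def run_all(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages in order and write ``report.json``.

    The report maps stage names to their tidy results (lists of records)
    plus a provenance block with the config hash, seed, and package
    version.  Per-cancer failures are recorded under ``skipped`` and do
    not abort the run.
    """
    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "package": "splicestrat",
            "version": __version__,
            "config_hash": cfg.config_hash(),
            "seed": cfg.seed,
        },
        "skipped": [],
    }

    def read_back(path: Path | None) -> list[dict] | str:
        if path is None:
            return "not run"
        df = pd.read_csv(path, comment="#")
        return json.loads(df.to_json(orient="records"))

    stages = [
        ("expression", stage_quantify),
        ("groups", stage_stratify),
        ("diffexp", stage_diffexp),
        ("survival", stage_survival),
        ("protein", stage_protein),
        ("variants", stage_variants),
    ]
    for name, fn in stages:
        try:
            path = fn(cfg, outdir)
        except SpliceStratError as exc:
            logger.error("stage %s failed: %s", name, exc)
            report["skipped"].append({"stage": name, "reason": str(exc)})
            continue
        if name == "expression":
            report[name] = {"path": Path(path).name}
        elif name == "survival":
            report["logrank"] = read_back(path)
            report["cox"] = read_back(outdir / "cox.csv")
        elif name == "variants":
            report[name] = ("not run" if path is None
                            else {"tally": Path(path).name})
        else:
            report[name] = read_back(path)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
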