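"""Seeded synthetic cohort generator for end-to-end pipeline testing.

The generator emulates the statistical structure the analysis assumes for
a TCGA-like cohort, per cancer type:

* the full-length isoform's discriminating-junction counts are negative
  binomial with mean ``p85_mean_normal`` in normals and a tumor mean
  shifted by ``2**p85_log2_shift_tumor`` (negative = downregulation in
  tumors, the tumor-suppressor pattern);
* the alternative-first-exon isoform's counts are zero-inflated negative
  binomial -- a point mass at zero (probability ``p55_zero_prob_*``) plus
  an overdispersed positive component -- because the downstream
  stratification rule (low iff count == 0) presupposes exactly that shape;
* clinical covariates (race with configurable mixture, age, sex, stage,
  smoking, alcohol) and proportional-hazards survival times: exponential
  with per-subject hazard ``lambda0 * exp(sum(beta * x))``, censored at
  the minimum of a uniform censoring time and an administrative horizon;
* an RPPA-like protein table whose per-protein group effects follow the
  isoform grouping; and
* a planted variant fixture whose region/class tally is known exactly.

Randomness is organised as one stream per component (junctions, clinical,
survival, protein, variants), spawned from the single config seed, so the
same seed reproduces every table byte-for-byte and adding samples to one
component never perturbs another.
"""

from __future__ import annotations

import dataclasses
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .junctions import (
    GenomicJunction,
    JunctionMatrix,
    P55A_JUNCTION,
    P85A_JUNCTION,
)
from .stratify import split_by_mean
from .variants import (
    CONSEQUENCE_CLASSES,
    ConsequenceTally,
    RegionSet,
    VariantRecord,
    default_pik3r1_regions,
    tally_consequences,
)

__all__ = ["SimConfig", "SimBundle", "PlantedVariants", "simulate_cohort",
           "planted_variant_fixture", "nb_draws", "zinb_draws"]


def _default_race_props() -> dict[str, float]:
    return {"AA": 0.20, "EA": 0.75, "OTHER": 0.05}


def _default_log_hr() -> dict[str, float]:
    # per-day baseline hazard multiplied by exp of these terms
    return {
        "p85_low": 0.5,  # ~ HR 1.65 for low p85a expression
        "age_per_year": 0.02,  # centered at 60 years
        "stage_advanced": 0.7,
        "race_AA": 0.2,
    }


def _default_protein_effects() -> dict[str, float]:
    # additive shift (in RPPA z-score units) for the high-p55a group
    return {
        "AKT": 0.3,
        "AKT1_2_3": 0.2,
        "AKT_pS473": 0.8,
        "AKT_pT308": 0.6,
        "mTOR": 0.0,
        "mTOR_pS2448": 0.5,
        "p53": 0.0,
        "PTEN": -0.5,
    }


def _default_planted_counts() -> dict[str, dict[str, int]]:
    # region -> consequence class -> count; scaled-down shape of a
    # two-region gnomAD tally with a handful of shared variants
    return {
        "p85a": {"5_prime_UTR": 4, "intron": 20, "splice_region": 2,
                 "splice_donor": 1, "missense": 3, "synonymous": 2},
        "p55a": {"intron": 6, "splice_region": 1},
        "shared": {"intron": 2, "splice_region": 1},
    }


@dataclass
class SimConfig:
    """All synthetic-cohort parameters; one seed drives every stream."""

    cancers: tuple[str, ...] = ("BRCA",)
    n_tumor: int = 100
    n_normal: int = 100
    race_props: dict[str, float] = field(default_factory=_default_race_props)
    # p85a discriminating junction: NB(mean, dispersion); tumors shifted
    p85_mean_normal: float = 150.0
    p85_log2_shift_tumor: float = -1.0
    p85_dispersion: float = 8.0
    # p55a: zero-inflated NB
    p55_zero_prob_normal: float = 0.8
    p55_zero_prob_tumor: float = 0.4
    p55_mean: float = 20.0
    p55_dispersion: float = 5.0
    # unrelated background junctions padding the matrix
    n_background_junctions: int = 20
    background_mean: float = 30.0
    # survival
    baseline_hazard: float = 1.0 / 1500.0  # events per day
    log_hr: dict[str, float] = field(default_factory=_default_log_hr)
    censor_upper: float = 3000.0  # uniform censoring upper bound, days
    admin_horizon: float = 3650.0  # administrative cutoff, days
    pfi_hazard_ratio: float = 1.5  # progression hazard relative to death
    # protein table
    protein_effects: dict[str, float] = field(default_factory=_default_protein_effects)
    protein_noise_sd: float = 1.0
    # variant fixture
    planted_counts: dict[str, dict[str, int]] = field(
        default_factory=_default_planted_counts
    )
    seed: int = 0

    def validate(self) -> None:
        def check(cond: bool, name: str, msg: str) -> None:
            if not cond:
                raise ConfigError(f"SimConfig.{name}: {msg}")

        check(len(self.cancers) >= 1, "cancers", "at least one cancer code")
        check(self.n_tumor >= 0 and self.n_normal >= 0, "n_tumor/n_normal", ">= 0")
        check(
            abs(sum(self.race_props.values()) - 1.0) < 1e-9,
            "race_props",
            "proportions must sum to 1",
        )
        check(all(0 <= p <= 1 for p in self.race_props.values()),
              "race_props", "proportions in [0, 1]")
        for name in ("p85_mean_normal", "p85_dispersion", "p55_mean",
                     "p55_dispersion", "background_mean"):
            check(getattr(self, name) > 0, name, "must be > 0")
        for name in ("p55_zero_prob_normal", "p55_zero_prob_tumor"):
            check(0 <= getattr(self, name) <= 1, name, "probability in [0, 1]")
        check(self.baseline_hazard > 0, "baseline_hazard", "must be > 0")
        check(self.censor_upper > 0, "censor_upper", "must be > 0")
        check(self.admin_horizon > 0, "admin_horizon", "must be > 0")
        check(self.n_background_junctions >= 0, "n_background_junctions", ">= 0")
        check(self.protein_noise_sd > 0, "protein_noise_sd", "must be > 0")
        for region, classes in self.planted_counts.items():
            check(region in ("p85a", "p55a", "shared", "outside"),
                  "planted_counts", f"unknown region {region!r}")
            for cls, n in classes.items():
                check(cls in CONSEQUENCE_CLASSES, "planted_counts",
                      f"unknown consequence class {cls!r}")
                check(n >= 0, "planted_counts", "counts must be >= 0")

    # -- config file round trip -------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["cancers"] = list(self.cancers)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping of SimConfig fields")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown SimConfig fields {sorted(unknown)}")
        if "cancers" in data:
            data["cancers"] = tuple(data["cancers"])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    def config_hash(self) -> str:
        payload = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def nb_draws(rng: np.random.Generator, mean: float, dispersion: float, size) -> np.ndarray:
    """Negative binomial draws parameterized by mean and size (dispersion).

    ``dispersion`` is the NB size parameter r; variance = mean + mean^2/r.
    """
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p, size=size)


def zinb_draws(
    rng: np.random.Generator, zero_prob: float, mean: float, dispersion: float, size
) -> np.ndarray:
    """Zero-inflated NB: structural zero w.p. ``zero_prob``, else NB."""
    zeros = rng.random(size) < zero_prob
    counts = nb_draws(rng, mean, dispersion, size)
    counts = np.where(counts == 0, 1, counts)  # positive component stays > 0
    return np.where(zeros, 0, counts)


@dataclass
class SimBundle:
    """One simulated cohort in exactly the formats the analysis reads."""

    junction_matrix: JunctionMatrix
    clinical: pd.DataFrame
    protein: pd.DataFrame  # samples x proteins
    variants: pd.DataFrame  # variant TSV-shaped table
    expected_tally: ConsequenceTally
    config: SimConfig

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write junctions.tsv, clinical.csv, protein.csv, variants.tsv."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "junctions": outdir / "junctions.tsv",
            "clinical": outdir / "clinical.csv",
            "protein": outdir / "protein.csv",
            "variants": outdir / "variants.tsv",
            "config": outdir / "sim_config.yaml",
        }
        self.junction_matrix.write_tsv(paths["junctions"])
        self.clinical.to_csv(paths["clinical"], index=False, float_format="%.10g")
        self.protein.to_csv(paths["protein"], float_format="%.12g")
        self.variants.to_csv(paths["variants"], sep="\t", index=False)
        self.config.to_yaml(paths["config"])
        return paths


_RACE_STRINGS = {
    "AA": "BLACK OR AFRICAN AMERICAN",
    "EA": "WHITE",
    "OTHER": "ASIAN",
}


def _component_rng(cfg: SimConfig, component: str) -> np.random.Generator:
    """Deterministic per-component stream derived from the config seed."""
    digest = int.from_bytes(
        hashlib.sha256(component.encode()).digest()[:4], "little"
    )
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, digest]))


def simulate_cohort(cfg: SimConfig | None = None) -> SimBundle:
    """Generate a complete synthetic cohort from a validated config.

    Draw order is fixed: per cancer, junction counts (normals then tumors,
    p85a then p55a then background), then clinical covariates, then
    survival, then protein, then the variant fixture -- each from its own
    seeded stream.
    """
    cfg = SimConfig() if cfg is None else cfg
    cfg.validate()
    rng_j = _component_rng(cfg, "junctions")
    rng_c = _component_rng(cfg, "clinical")
    rng_s = _component_rng(cfg, "survival")
    rng_p = _component_rng(cfg, "protein")

    race_levels = list(cfg.race_props)
    race_p = np.array([cfg.race_props[r] for r in race_levels])

    all_samples: list[str] = []
    sample_cancer: list[str] = []
    sample_type: list[str] = []
    p85_counts: list[np.ndarray] = []
    p55_counts: list[np.ndarray] = []
    bg_counts: list[np.ndarray] = []
    clin_rows: list[dict] = []

    p85_mean_tumor = cfg.p85_mean_normal * 2.0**cfg.p85_log2_shift_tumor
    for cancer in cfg.cancers:
        normals = [f"{cancer}-NORM-{i:04d}" for i in range(cfg.n_normal)]
        tumors = [f"{cancer}-TUMOR-{i:04d}" for i in range(cfg.n_tumor)]
        # junction stream: normals then tumors, isoform by isoform
        p85 = np.concatenate([
            nb_draws(rng_j, cfg.p85_mean_normal, cfg.p85_dispersion, cfg.n_normal),
            nb_draws(rng_j, p85_mean_tumor, cfg.p85_dispersion, cfg.n_tumor),
        ])
        p55 = np.concatenate([
            zinb_draws(rng_j, cfg.p55_zero_prob_normal, cfg.p55_mean,
                       cfg.p55_dispersion, cfg.n_normal),
            zinb_draws(rng_j, cfg.p55_zero_prob_tumor, cfg.p55_mean,
                       cfg.p55_dispersion, cfg.n_tumor),
        ])
        bg = nb_draws(
            rng_j, cfg.background_mean, 5.0,
            (cfg.n_background_junctions, cfg.n_normal + cfg.n_tumor),
        )
        samples = normals + tumors
        all_samples += samples
        sample_cancer += [cancer] * len(samples)
        sample_type += ["normal"] * cfg.n_normal + ["tumor"] * cfg.n_tumor
        p85_counts.append(p85)
        p55_counts.append(p55)
        bg_counts.append(bg)

        # clinical stream
        races = rng_c.choice(race_levels, p=race_p, size=len(samples))
        ages = np.clip(rng_c.normal(60.0, 10.0, len(samples)), 20.0, 95.0)
        sexes = rng_c.choice(["FEMALE", "MALE"], size=len(samples))
        stages = rng_c.choice(
            ["Stage I", "Stage II", "Stage III", "Stage IV"],
            p=[0.3, 0.3, 0.25, 0.15], size=len(samples),
        )
        smoking = rng_c.choice(["YES", "NO"], p=[0.4, 0.6], size=len(samples))
        alcohol = rng_c.choice(["YES", "NO"], p=[0.5, 0.5], size=len(samples))

        # survival stream: hazard depends on the (latent) p85a group,
        # recovered by the same per-cancer mean split the analysis uses
        tumor_log = np.log10(p85[cfg.n_normal:] + 1.0)
        if cfg.n_tumor >= 2:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                labels = split_by_mean(tumor_log, barcodes=tumors)
            low = np.array([gl.label == "low" for gl in labels])
        else:
            low = np.zeros(cfg.n_tumor, dtype=bool)
        low_all = np.concatenate([np.zeros(cfg.n_normal, dtype=bool), low])
        advanced = np.array([s in ("Stage III", "Stage IV") for s in stages])
        loghaz = (
            cfg.log_hr.get("p85_low", 0.0) * low_all
            + cfg.log_hr.get("age_per_year", 0.0) * (ages - 60.0)
            + cfg.log_hr.get("stage_advanced", 0.0) * advanced
            + cfg.log_hr.get("race_AA", 0.0) * (races == "AA")
        )
        os_haz = cfg.baseline_hazard * np.exp(loghaz)
        t_event = rng_s.exponential(1.0 / os_haz)
        t_cens = rng_s.uniform(0.0, cfg.censor_upper, len(samples))
        t_cens = np.minimum(t_cens, cfg.admin_horizon)
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
        t_prog = rng_s.exponential(1.0 / (os_haz * cfg.pfi_hazard_ratio))
        pfi_time = np.minimum(t_prog, t_cens)
        pfi_event = (t_prog <= t_cens).astype(int)

        for i, barcode in enumerate(samples):
            clin_rows.append(
                {
                    "bcr_patient_barcode": barcode,
                    "type": cancer,
                    "sample_type": "normal" if i < cfg.n_normal else "tumor",
                    "race": _RACE_STRINGS[races[i]],
                    "age": round(float(ages[i]), 1),
                    "gender": sexes[i],
                    "ajcc_stage": stages[i],
                    "smoking_history": smoking[i],
                    "alcohol_history": alcohol[i],
                    "OS_time": round(float(os_time[i]), 2),
                    "OS_event": int(os_event[i]),
                    "PFI_time": round(float(pfi_time[i]), 2),
                    "PFI_event": int(pfi_event[i]),
                }
            )

    junctions = [P85A_JUNCTION, P55A_JUNCTION] + [
        GenomicJunction("chr5", 69_000_000 + 1000 * i, 69_000_400 + 1000 * i, "+")
        for i in range(cfg.n_background_junctions)
    ]
    counts = np.vstack(
        [
            np.concatenate(p85_counts),
            np.concatenate(p55_counts),
        ]
        + ([np.hstack(bg_counts)] if cfg.n_background_junctions else [])
    )
    jm = JunctionMatrix(junctions, all_samples, counts).sorted()
    clinical = pd.DataFrame(clin_rows)

    # protein stream: tumors only, shifted for the p55a-expressing group
    tumor_mask = np.array(sample_type) == "tumor"
    tumor_barcodes = [s for s, m in zip(all_samples, tumor_mask) if m]
    p55_all = np.concatenate(p55_counts)
    high_p55 = p55_all[tumor_mask] > 0
    proteins = list(cfg.protein_effects)
    values = (
        np.outer(high_p55, [cfg.protein_effects[p] for p in proteins])
        + rng_p.normal(0.0, cfg.protein_noise_sd, (len(tumor_barcodes), len(proteins)))
    )
    protein = pd.DataFrame(values, index=pd.Index(tumor_barcodes, name="sample_barcode"),
                           columns=proteins)

    planted = planted_variant_fixture(cfg)
    return SimBundle(
        junction_matrix=jm,
        clinical=clinical,
        protein=protein,
        variants=planted.variants,
        expected_tally=planted.expected_tally,
        config=cfg,
    )


@dataclass
class PlantedVariants:
    variants: pd.DataFrame  # chrom, pos, ref, alt, rsid, consequence
    expected_tally: ConsequenceTally
    regions: RegionSet
    # coding-SNV worked example planted in the table: a CDS whose codon 6
    # is TGG so that c.18G>T gives the Trp->Cys missense
    coding_example: tuple[str, int, str, str] = (
        "ATG" + "GCT" * 4 + "TGG" + "GCT" * 4, 18, "G", "T",
    )


def planted_variant_fixture(cfg: SimConfig | None = None) -> PlantedVariants:
    """Emit a variant table whose region/class tally is known exactly.

    Variants destined for one region get consecutive positions inside that
    region's exclusive part; "shared" plants sit on the single coordinate
    common to both regions; "outside" plants sit upstream of both.  The
    expected tally is computed with :func:`tally_consequences` itself on
    the emitted records, but its per-class counts are guaranteed (and
    tested) to equal the planted configuration.
    """
    cfg = SimConfig() if cfg is None else cfg
    cfg.validate()
    regions = default_pik3r1_regions()
    pos_cursor = {
        "p85a": regions.start_a,  # exclusive part: [start_a, end_a)
        "p55a": regions.start_b + 1,  # exclusive part: (start_b, end_b]
        "shared": regions.end_a,  # the single overlapping coordinate
        "outside": 1_000,
    }
    limits = {
        "p85a": regions.end_a - 1,  # exclusive part must stay off the boundary
        "p55a": regions.end_b,
        "shared": regions.end_a,
        "outside": regions.start_a - 1,
    }
    bases = ["A", "C", "G", "T"]
    rows = []
    rs_counter = 900_000
    for region in ("p85a", "p55a", "shared", "outside"):
        for cls, n in sorted(cfg.planted_counts.get(region, {}).items()):
            for _ in range(n):
                pos = pos_cursor[region]
                if pos > limits[region]:
                    raise ConfigError(
                        f"planted_counts for region {region!r} exceed the "
                        "region's coordinate capacity"
                    )
                if region != "shared":  # shared plants stack on one coordinate
                    pos_cursor[region] += 1
                ref = bases[pos % 4]
                alt = bases[(pos + 1 + rs_counter) % 4]
                if alt == ref:
                    alt = bases[(pos + 2 + rs_counter) % 4]
                rows.append(
                    {
                        "chrom": "5",
                        "pos": pos,
                        "ref": ref,
                        "alt": alt,
                        "rsid": f"rs{rs_counter}",
                        "consequence": cls,
                    }
                )
                rs_counter += 1
    variants = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "rsid", "consequence"]
    )
    records = [
        VariantRecord(r.chrom, int(r.pos), r.ref, r.alt, r.rsid, r.consequence)
        for r in variants.itertuples(index=False)
    ]
    expected = tally_consequences(records, regions)
    return PlantedVariants(variants=variants, expected_tally=expected, regions=regions)
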