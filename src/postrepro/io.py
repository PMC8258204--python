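"""Dataset container, CSV formats, and pipeline orchestration.

A sighting dataset is two CSV files:

``metadata.csv``
    columns ``id, sex, birth_year, death_year``; sex in {F, M, U};
    a birth or death year of 0 means unknown (to be treated as a
    latent variable by the inference).

``sightings.csv``
    first column ``id``, remaining columns calendar years, cells 0/1 --
    the yearly presence/absence capture-mark-recapture matrix.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("postrepro")

__all__ = [
    "SightingDataset",
    "read_dataset",
    "write_dataset",
    "RunConfig",
    "run_pipeline",
]

_SEXES = ("F", "M", "U")


@dataclass
class SightingDataset:
    """Per-individual metadata plus the yearly 0/1 detection matrix."""

    meta: pd.DataFrame          # id, sex, birth_year, death_year
    matrix: pd.DataFrame        # index id, columns calendar years (int)
    study_start: int
    study_end: int

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------
    def validate(self) -> None:
        meta, mat = self.meta, self.matrix
        required = {"id", "sex", "birth_year", "death_year"}
        if not required.issubset(meta.columns):
            raise ValueError(f"metadata missing columns {required - set(meta.columns)}")
        if meta["id"].duplicated().any():
            dups = meta.loc[meta["id"].duplicated(), "id"].tolist()
            raise ValueError(f"duplicate ids in metadata: {dups[:5]}")
        bad_sex = set(meta["sex"]) - set(_SEXES)
        if bad_sex:
            raise ValueError(f"invalid sex codes: {sorted(bad_sex)}")
        if set(meta["id"]) != set(mat.index):
            raise ValueError("metadata and sighting matrix ids disagree")
        years = np.asarray(mat.columns, int)
        if years[0] != self.study_start or years[-1] != self.study_end:
            raise ValueError("sighting-matrix years do not span the study window")
        vals = mat.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("sighting matrix cells must be 0 or 1")
        # detections must respect known birth/death years
        mat_al = mat.loc[meta["id"]].to_numpy()
        det_any = mat_al.sum(axis=1) > 0
        first = np.where(det_any, (mat_al * 1).argmax(axis=1), -1)
        last = np.where(det_any, len(years) - 1 - mat_al[:, ::-1].argmax(axis=1), -1)
        birth = meta["birth_year"].to_numpy()
        death = meta["death_year"].to_numpy()
        bad = det_any & (birth > 0) & (years[first] < birth)
        if bad.any():
            raise ValueError(
                f"detection before known birth year for ids "
                f"{meta.loc[bad, 'id'].tolist()[:5]}"
            )
        bad = det_any & (death > 0) & (years[last] > death)
        if bad.any():
            raise ValueError(
                f"detection after known death year for ids "
                f"{meta.loc[bad, 'id'].tolist()[:5]}"
            )

    # -- convenience ------------------------------------------------
    @property
    def years(self) -> np.ndarray:
        return np.asarray(self.matrix.columns, int)

    @property
    def n_individuals(self) -> int:
        return len(self.meta)

    def detection_years(self) -> pd.DataFrame:
        """First and last detection year per individual (NaN if never seen)."""
        mat = self.matrix.loc[self.meta["id"]].to_numpy()
        years = self.years
        any_det = mat.sum(axis=1) > 0
        first = np.where(any_det, years[(mat * 1).argmax(axis=1)], np.nan)
        last = np.where(any_det,
                        years[len(years) - 1 - mat[:, ::-1].argmax(axis=1)], np.nan)
        return pd.DataFrame(
            {"id": self.meta["id"], "first": first, "last": last}
        ).set_index("id")

    def with_sexes(self, sexes: pd.Series | dict) -> "SightingDataset":
        """Copy of the dataset with (some) sexes replaced (id -> F/M)."""
        meta = self.meta.copy()
        mapping = dict(sexes) if not isinstance(sexes, dict) else sexes
        meta["sex"] = meta.apply(
            lambda r: mapping.get(r["id"], r["sex"]), axis=1
        )
        return SightingDataset(meta, self.matrix, self.study_start, self.study_end)


def read_dataset(metadata_csv, sightings_csv) -> SightingDataset:
    """Read and validate the two-file CSV dialect."""
    meta = pd.read_csv(metadata_csv, dtype={"id": str})
    if "mother_id" in meta.columns:
        meta["mother_id"] = meta["mother_id"].fillna("").astype(str)
    mat = pd.read_csv(sightings_csv, dtype={"id": str}).set_index("id")
    mat.columns = mat.columns.astype(int)
    years = np.asarray(mat.columns, int)
    if not (np.diff(years) == 1).all():
        raise ValueError("sighting-matrix years must be consecutive")
    return SightingDataset(meta, mat, int(years[0]), int(years[-1]))


def write_dataset(data: SightingDataset, metadata_csv, sightings_csv) -> None:
    """Write the canonical CSV representation (round-trips byte-identically)."""
    cols = ["id", "sex", "birth_year", "death_year"]
    if "mother_id" in data.meta.columns:
        cols.append("mother_id")
    meta = data.meta[cols]
    meta.to_csv(metadata_csv, index=False, lineterminator="\n")
    mat = data.matrix.loc[meta["id"]]
    mat.index.name = "id"
    mat.to_csv(sightings_csv, lineterminator="\n")


# ---------------------------------------------------------------------------
# pipeline orchestration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Fully explicit configuration of one pipeline run.

    The ``paper`` preset encodes the full published MCMC schedule
    (4 chains of 1,000,000 iterations, 200,001 burn-in, 10,001 thinning,
    1,000 sex permutations, 9,999 null populations); the ``desk`` preset
    is a small-scale configuration for interactive use and testing.
    """

    outdir: str = "postrepro_out"
    metadata_csv: Optional[str] = None
    sightings_csv: Optional[str] = None
    model: str = "gompertz"
    shape: str = "bathtub"
    preset: str = "desk"
    seed: int = 1
    n_perm: int = 0                  # 0 = single fit, no sex permutations
    n_null: int = 999
    n_pop: int = 1000
    maturity_age: int = 10
    null_birth_rate: float = 0.2
    adult_age: int = 13
    max_age: int = 100
    # MCMC schedule; None = take from preset
    n_chains: Optional[int] = None
    n_iterations: Optional[int] = None
    burn_in: Optional[int] = None
    thinning: Optional[int] = None
    prior_overrides: dict = field(default_factory=dict)
    kinship_scenarios: list = field(default_factory=list)

    def mcmc(self):
        from postrepro.cmr import MCMCConfig

        base = (MCMCConfig.paper_preset(self.seed) if self.preset == "paper"
                else MCMCConfig.desk_preset(self.seed))
        return dataclasses.replace(
            base,
            n_chains=self.n_chains or base.n_chains,
            n_iterations=self.n_iterations or base.n_iterations,
            burn_in=self.burn_in or base.burn_in,
            thinning=self.thinning or base.thinning,
        )

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        m = self.mcmc()
        d.update(n_chains=m.n_chains, n_iterations=m.n_iterations,
                 burn_in=m.burn_in, thinning=m.thinning)
        if self.preset == "paper":
            d.setdefault("n_perm_preset", 1000)
            d["n_null"] = max(self.n_null, 9999)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.resolved(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


def _stamp(config: RunConfig) -> dict:
    return {"config_hash": config.config_hash(), "seed": config.seed}


def run_pipeline(config: RunConfig, data: Optional[SightingDataset] = None) -> dict:
    """Run the full analysis and write a report bundle to ``config.outdir``.

    Stages: load data, Bayesian survival fit (with optional unknown-sex
    permutations), survivorship envelope and life table, fecundity
    schedule with ages B/M, life-span summaries, PrR with its null
    simulation test, and optional kinship scenarios.  Every output file
    carries the configuration hash and master seed so runs can be
    reproduced exactly.
    """
    from postrepro import cmr, kinship, lifetable, prr
    from postrepro.mortality import Model, Shape, MortalityParams
    from postrepro.simulate import make_birth_records_from_dataset

    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stamp": _stamp(config), "stages": []}

    def stage(name):
        logger.info("pipeline stage: %s", name)
        report["stages"].append(name)

    try:
        stage("load")
        if data is None:
            if not config.metadata_csv:
                raise ValueError("no dataset given and no input paths configured")
            data = read_dataset(config.metadata_csv, config.sightings_csv)
        report["n_individuals"] = int(data.n_individuals)

        stage("fit")
        mcmc = config.mcmc()
        priors = cmr.PriorSpec.default(Model(config.model), Shape(config.shape))
        for k, v in config.prior_overrides.items():
            priors = priors.with_param(k, *v)
        rng = np.random.default_rng(config.seed)
        if config.n_perm > 0:
            draws_list = cmr.permute_unknown_sexes(
                data, n_perm=config.n_perm, mcmc=mcmc,
                model=Model(config.model), shape=Shape(config.shape),
                priors=priors,
            )
            fits = [d for d, _ in draws_list if d is not None]
            reports = [r for d, r in draws_list if d is not None]
            if not fits:
                raise RuntimeError("every permutation fit failed")
        else:
            unknown = data.meta["sex"] == "U"
            if unknown.any():
                assign = {i: ("F" if rng.random() < 0.5 else "M")
                          for i in data.meta.loc[unknown, "id"]}
                data_fit = data.with_sexes(assign)
            else:
                data_fit = data
            d0, r0 = cmr.fit(data_fit, Model(config.model), Shape(config.shape),
                             priors=priors, mcmc=mcmc)
            fits, reports = [d0], [r0]
        conv = {
            "pass": all(r.passed for r in reports),
            "rhat_max": max(max(r.rhat.values()) for r in reports),
        }
        report["convergence"] = conv
        fits[0].to_frame().to_csv(out / "posterior.csv", index=False)

        stage("lifetable")
        ages = np.arange(config.max_age + 1)
        env = lifetable.lx_from_draws(fits, "F", ages)
        table = lifetable.LifeTable.from_lx(ages, env["median"].to_numpy())
        tf = table.to_frame()
        tf.to_csv(out / "lifetable_female.csv", index=False)
        avg, l90 = lifetable.lifespan_summaries(table)
        env_m = lifetable.lx_from_draws(fits, "M", ages)
        table_m = lifetable.LifeTable.from_lx(ages, env_m["median"].to_numpy())
        avg_m, l90_m = lifetable.lifespan_summaries(table_m)
        report["lifespan"] = {
            "female": {"average": round(avg, 1), "p90": round(l90, 1)},
            "male": {"average": round(avg_m, 1), "p90": round(l90_m, 1)},
        }

        stage("fecundity")
        records = make_birth_records_from_dataset(data)
        sched = lifetable.estimate_mx(records)
        sched.to_frame().to_csv(out / "fecundity.csv", index=False)
        B, M = lifetable.ages_B_M(sched)
        report["reproductive_span"] = {
            "B": B, "M": M,
            "e_B": round(float(table.at(B)[1]), 1),
            "e_M": round(float(table.at(M)[1]), 1),
        }

        stage("prr")
        params_med = fits[0].posterior_median_params("F")
        prr_obs = prr.compute_prr(table, B, M)
        res = prr.prr_significance(
            prr_obs, params_med, n_null=config.n_null, n_pop=config.n_pop,
            rng=np.random.default_rng(config.seed + 1),
            maturity_age=config.maturity_age,
            birth_rate=config.null_birth_rate,
        )
        report["prr"] = {
            "value": float(prr_obs),
            "p_value": float(res.p_value[0]),
            "null_median": float(res.null_quantiles["median"]),
        }
        with open(out / "prr.json", "w") as fh:
            json.dump({**_stamp(config), **res.to_dict()}, fh, indent=2,
                      sort_keys=True)

        if config.kinship_scenarios:
            stage("kinship")
            scen = [kinship.KinshipScenario(**s) for s in config.kinship_scenarios]
            traj = kinship.compare_scenarios(scen, seed=config.seed + 2)
            traj.to_csv(out / "kinship.csv", index=False)

        stage("done")
    except Exception as exc:  # persist partial results before propagating
        report["error"] = {"stage": report["stages"][-1], "message": str(exc)}
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True, default=float)
        raise

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
    return report
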