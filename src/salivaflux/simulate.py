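"""Synthetic paired-cohort generator.

Emulates the causal structure the downstream analysis assumes for a
type-2-diabetes (T2D) vs normoglycemic cohort sampled in three fluids:

* hyperglycemia elevates plasma glucose and fructose (log-normal
  intensities, ``glycemia_shift`` on the log10 scale);
* a latent migration variable M_i — the mean of the standardized log
  plasma glucose and fructose, attenuated by the glandular transfer
  fraction — drives glandular-saliva saccharide levels;
* whole-saliva levels are the glandular levels further depleted in
  proportion to the cariogenic (positively responding) fraction of the
  supragingival community, so Spearman correlations between glycemic
  markers and saccharide levels decay from plasma to glandular to whole
  saliva;
* taxon log-abundances respond linearly to M_i with signed per-taxon
  effects (positive = cariogenic-like, negative = health-associated-like)
  and are closed to relative abundances;
* the caries count is Poisson with log-rate linear in M_i, capped at 28
  teeth.

Everything is driven by one integer seed; identical parameters and seed
reproduce the cohort bit for bit. The latent truth (M_i, taxon effects,
caries link) is always emitted so tests never re-derive it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields

import numpy as np
import pandas as pd

from .containers import FeatureTable, MetaboliteTable

FLUIDS = ("plasma", "glandular", "whole")

__all__ = [
    "SimulationParams",
    "SyntheticCohort",
    "generate_cohort",
    "generate_injection_sequence",
]


@dataclass
class SimulationParams:
    """Generator settings; defaults mirror the emulated study design.

    ``taxon_effect`` may be a full per-taxon vector; by default the
    first 10 % of taxa respond positively (+0.5, cariogenic-like), the
    next 10 % negatively (-0.5, health-associated-like), the rest are
    null.
    """

    n_control: int = 30
    n_t2d: int = 31
    n_metabolites: int = 60
    n_taxa: int = 80
    glycemia_shift: float = 0.4      # log10 plasma saccharide elevation in T2D
    gland_transfer: float = 0.6      # fraction of plasma log-signal reaching glandular saliva
    consumption_strength: float = 1.0  # whole-saliva log10 depletion per unit cariogenic load
    taxon_effect: np.ndarray | None = None  # per-taxon log10 response to M_i
    effect_size: float = 0.5         # magnitude used when taxon_effect is None
    caries_link: float = 0.5         # coefficient of M_i in the Poisson caries log-rate
    noise_sd: float = 0.2            # residual sd, log10 scale
    seed: int = 0
    simulate_post: bool = True       # add day-14 samples for T2D participants
    post_shift_fraction: float = 0.25  # residual glycemia shift after treatment

    def resolved_taxon_effect(self) -> np.ndarray:
        if self.taxon_effect is not None:
            eff = np.asarray(self.taxon_effect, dtype=float)
            if eff.shape != (self.n_taxa,):
                raise ValueError("taxon_effect must have length n_taxa")
            return eff
        k = max(int(round(0.1 * self.n_taxa)), 1)
        eff = np.zeros(self.n_taxa)
        eff[:k] = self.effect_size
        eff[k:2 * k] = -self.effect_size
        return eff

    def validate(self) -> None:
        if self.n_control < 1:
            raise ValueError("n_control must be >= 1")
        if self.n_t2d < 1:
            raise ValueError("n_t2d must be >= 1")
        if self.n_metabolites < 5:
            raise ValueError("n_metabolites must be >= 5")
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0 < self.gland_transfer <= 1:
            raise ValueError("gland_transfer must be in (0, 1]")
        if self.consumption_strength < 0:
            raise ValueError("consumption_strength must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        self.resolved_taxon_effect()

    def to_dict(self) -> dict:
        d = {}
        for f in fields(self):
            v = getattr(self, f.name)
            d[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return d


@dataclass
class SyntheticCohort:
    metabolite_tables: dict            # fluid → MetaboliteTable
    feature_table: FeatureTable
    cohort: pd.DataFrame               # one row per participant-timepoint
    truth: dict = field(default_factory=dict)


# log10 mean plasma intensities of the two saccharides in controls;
# glandular and whole-saliva levels derive from these via the transfer
# fraction and microbial consumption, so the couplings stay literal
_BASE_LEVELS = {"plasma": {"glucose": 3.0, "fructose": 2.4}}
_IS_INTENSITY = 1000.0  # ribitol spiked at fixed concentration
_MAX_TEETH = 28


def generate_cohort(params: SimulationParams) -> SyntheticCohort:
    """Draw one synthetic cohort with paired fluids, taxa and clinical data."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    eff = params.resolved_taxon_effect()

    pids = [f"C{i+1:03d}" for i in range(params.n_control)] + [
        f"T{i+1:03d}" for i in range(params.n_t2d)
    ]
    groups = ["control"] * params.n_control + ["t2d"] * params.n_t2d

    records = []  # (sample_id, participant, group, timepoint, shift)
    for pid, grp in zip(pids, groups):
        shift = params.glycemia_shift if grp == "t2d" else 0.0
        records.append((f"{pid}_baseline", pid, grp, "baseline", shift))
        if grp == "t2d" and params.simulate_post:
            records.append(
                (f"{pid}_post", pid, grp, "post",
                 params.glycemia_shift * params.post_shift_fraction)
            )
    sample_ids = [r[0] for r in records]
    n_samples = len(records)
    shifts = np.array([r[4] for r in records])
    is_baseline = np.array([r[3] == "baseline" for r in records])

    noise = params.noise_sd

    # --- plasma saccharides (log10) -------------------------------------
    lp_glc = _BASE_LEVELS["plasma"]["glucose"] + shifts + noise * rng.standard_normal(n_samples)
    lp_fru = (_BASE_LEVELS["plasma"]["fructose"] + 0.8 * shifts
              + noise * rng.standard_normal(n_samples))

    # --- latent migration -----------------------------------------------
    # standardize against the baseline cross-section so post-treatment
    # samples are measured on the same scale
    def _z(x: np.ndarray) -> np.ndarray:
        mu, sd = x[is_baseline].mean(), x[is_baseline].std(ddof=0)
        sd = sd if sd > 0 else 1.0
        return (x - mu) / sd

    M = params.gland_transfer * 0.5 * (_z(lp_glc) + _z(lp_fru))

    # --- glandular saliva: attenuated transfer + noise ------------------
    lg_glc = params.gland_transfer * lp_glc + noise * rng.standard_normal(n_samples)
    lg_fru = params.gland_transfer * lp_fru + noise * rng.standard_normal(n_samples)

    # --- supragingival taxa ---------------------------------------------
    # responsive marker taxa are moderately abundant community members
    # (their real-world counterparts are common species), so they clear
    # the 0.1 % abundance prefilter; background taxa span a wider range
    base_taxa = rng.normal(0.0, 1.0, size=params.n_taxa)
    base_taxa[eff != 0] = rng.normal(0.8, 0.5, size=int((eff != 0).sum()))
    log_taxa = (base_taxa[None, :] + eff[None, :] * M[:, None]
                + noise * rng.standard_normal((n_samples, params.n_taxa)))
    raw = 10.0 ** log_taxa
    rel = raw / raw.sum(axis=1, keepdims=True)
    cario_load = rel[:, eff > 0].sum(axis=1) if (eff > 0).any() else np.zeros(n_samples)

    # --- whole saliva: glandular minus microbial consumption ------------
    lw_glc = (lg_glc - params.consumption_strength * cario_load
              + noise * rng.standard_normal(n_samples))
    lw_fru = (lg_fru - params.consumption_strength * cario_load
              + noise * rng.standard_normal(n_samples))

    # --- caries and clinical covariates ---------------------------------
    pid_index = {pid: i for i, (sid, pid, grp, tp, s) in enumerate(records) if tp == "baseline"}
    M_baseline = np.array([M[pid_index[pid]] for pid in pids])
    caries = rng.poisson(np.exp(1.0 + params.caries_link * M_baseline))
    caries = np.minimum(caries, _MAX_TEETH)
    age = np.where(
        np.array(groups) == "t2d",
        rng.normal(64.0, 10.0, len(pids)),
        rng.normal(42.0, 11.0, len(pids)),
    )
    age = np.clip(np.round(age), 22, 85)
    gender = rng.choice(["female", "male"], size=len(pids))
    pisa = np.exp(rng.normal(np.log(150.0) + 0.3 * M_baseline, 0.7))
    flow = np.clip(rng.normal(0.7, 0.25, len(pids)), 0.05, None)
    plaque = np.clip(rng.normal(1.0 + 0.25 * M_baseline, 0.3), 0.0, 3.0)

    per_pid = pd.DataFrame(
        {
            "participant": pids, "group": groups, "age": age, "gender": gender,
            "caries_count": caries, "pisa": pisa, "salivary_flow": flow,
            "plaque_index": plaque,
        }
    ).set_index("participant")

    rows = []
    for i, (sid, pid, grp, tp, shift) in enumerate(records):
        glycemia = lp_glc[i] - _BASE_LEVELS["plasma"]["glucose"]
        rows.append(
            {
                "sample_id": sid, "participant": pid, "group": grp, "timepoint": tp,
                "age": per_pid.loc[pid, "age"], "gender": per_pid.loc[pid, "gender"],
                "hba1c": 5.4 + 3.0 * glycemia + 0.2 * rng.standard_normal(),
                "fpg": 90.0 + 120.0 * glycemia + 5.0 * rng.standard_normal(),
                "ga": 14.0 + 12.0 * glycemia + 0.8 * rng.standard_normal(),
                "caries_count": per_pid.loc[pid, "caries_count"],
                "pisa": per_pid.loc[pid, "pisa"],
                "plaque_index": per_pid.loc[pid, "plaque_index"],
                "salivary_flow": per_pid.loc[pid, "salivary_flow"],
            }
        )
    cohort = pd.DataFrame(rows).set_index("sample_id")

    # --- metabolite tables per fluid ------------------------------------
    levels = {
        "plasma": (lp_glc, lp_fru),
        "glandular": (lg_glc, lg_fru),
        "whole": (lw_glc, lw_fru),
    }
    n_extra = params.n_metabolites - 3  # glucose, fructose, ribitol
    extra_names = [f"met{i+1:03d}" for i in range(n_extra)]
    # two designated contaminant features whose signal also rides in blanks
    contaminants = set(extra_names[:2])
    extra_base = rng.normal(2.0, 0.4, size=n_extra)
    # a random fifth of background metabolites respond weakly to glycemia
    responsive = rng.random(n_extra) < 0.2
    extra_beta = np.where(responsive, 0.3, 0.0) * rng.choice([-1, 1], size=n_extra)

    metabolite_tables = {}
    for fluid in FLUIDS:
        glc, fru = levels[fluid]
        fluid_offset = {"plasma": 0.0, "glandular": -0.3, "whole": -0.1}[fluid]
        log_extra = (extra_base[None, :] + fluid_offset
                     + extra_beta[None, :] * shifts[:, None]
                     + noise * rng.standard_normal((n_samples, n_extra)))
        inj_scale = 10.0 ** rng.normal(0.0, 0.05, n_samples)  # per-injection response factor
        names = ["glucose", "fructose", "ribitol"] + extra_names
        if fluid == "glandular":
            amounts = rng.uniform(0.05, 0.25, n_samples)  # collected saliva mass, g
        else:
            amounts = np.full(n_samples, 1.0)             # fixed aliquot, mL
        # measured analyte signal scales with the collected amount, while the
        # internal standard is spiked at a fixed absolute quantity per vial
        mat = np.column_stack(
            [10.0**glc, 10.0**fru, np.full(n_samples, 1.0), 10.0**log_extra]
        ) * amounts[:, None]
        mat[:, names.index("ribitol")] = _IS_INTENSITY
        mat *= inj_scale[:, None]
        values = pd.DataFrame(mat, index=sample_ids, columns=names)
        sample_meta = pd.DataFrame(
            {
                "fluid": fluid,
                "participant": [r[1] for r in records],
                "timepoint": [r[3] for r in records],
                "injection_order": np.arange(n_samples),
                "batch": "b1",
                "role": "biological",
                "sample_amount": amounts,
            },
            index=values.index,
        )

        # two extraction blanks: ribitol present, contaminants at signal
        # level, everything else at trace intensity
        blank_rows = []
        for b in range(2):
            blank = 10.0 ** rng.normal(0.0, 0.3, len(names))
            blank[names.index("ribitol")] = _IS_INTENSITY * 10.0 ** rng.normal(0, 0.02)
            for c in contaminants:
                blank[names.index(c)] = 10.0 ** (extra_base[extra_names.index(c)]
                                                 + fluid_offset + rng.normal(0, 0.1))
            blank_rows.append(blank)
        blanks = pd.DataFrame(
            blank_rows, index=[f"blank{b+1}_{fluid}" for b in range(2)], columns=names
        )
        blank_meta = pd.DataFrame(
            {
                "fluid": fluid, "participant": None, "timepoint": None,
                "injection_order": np.arange(n_samples, n_samples + 2),
                "batch": "b1", "role": "blank", "sample_amount": np.nan,
            },
            index=blanks.index,
        )
        values = pd.concat([values, blanks])
        sample_meta = pd.concat([sample_meta, blank_meta])
        metabolite_meta = pd.DataFrame(
            {"internal_standard": [n == "ribitol" for n in names]}, index=names
        )
        metabolite_tables[fluid] = MetaboliteTable(values, sample_meta, metabolite_meta)

    taxa_names = [f"taxon{j+1:03d}" for j in range(params.n_taxa)]
    feature_values = pd.DataFrame(rel.T, index=taxa_names, columns=sample_ids)
    feature_meta = pd.DataFrame(
        {
            "level": "species",
            "phylum": np.where(eff > 0, "Actinomycetota",
                               np.where(eff < 0, "Bacillota", "Pseudomonadota")),
        },
        index=taxa_names,
    )
    feature_table = FeatureTable(feature_values, feature_meta)

    truth = {
        "M": pd.Series(M, index=sample_ids, name="M"),
        "cariogenic_load": pd.Series(cario_load, index=sample_ids, name="cariogenic_load"),
        "taxon_effect": pd.Series(eff, index=taxa_names, name="taxon_effect"),
        "caries_link": params.caries_link,
        "params": params.to_dict(),
    }
    return SyntheticCohort(metabolite_tables, feature_table, cohort, truth)


def generate_injection_sequence(
    table: MetaboliteTable,
    qc_interval: int = 6,
    drift=None,
) -> MetaboliteTable:
    """Insert pooled-QC injections and apply an instrument drift curve.

    Follows the acquisition convention of a pooled QC injected first and
    again after every ``qc_interval`` biological samples (a trailing QC
    is injected only when the final block is complete). The pooled QC is
    the mean of all biological samples' intensities. ``drift`` is a
    function of injection index multiplying every intensity; omit it for
    a drift-free sequence. Blank rows are injected after the sequence.
    """
    if qc_interval < 1:
        raise ValueError("qc_interval must be >= 1")
    bio_ids = list(table.sample_meta.index[table.sample_meta["role"] == "biological"])
    other_ids = [s for s in table.sample_meta.index if s not in set(bio_ids)]
    qc_profile = table.values.loc[bio_ids].mean(axis=0)

    order: list[tuple[str, str]] = [("qc", "QC001")]
    qc_count = 1
    for i, sid in enumerate(bio_ids, start=1):
        order.append(("biological", sid))
        if i % qc_interval == 0:
            qc_count += 1
            order.append(("qc", f"QC{qc_count:03d}"))
    for sid in other_ids:
        order.append((table.sample_meta.loc[sid, "role"], sid))

    new_values = {}
    new_meta = {}
    for idx, (role, sid) in enumerate(order):
        if role == "qc" and sid.startswith("QC"):
            new_values[sid] = qc_profile.copy()
            meta = {
                "fluid": table.sample_meta["fluid"].iloc[0],
                "participant": None, "timepoint": None,
                "injection_order": idx, "batch": table.sample_meta["batch"].iloc[0],
                "role": "qc", "sample_amount": np.nan,
            }
        else:
            new_values[sid] = table.values.loc[sid].copy()
            meta = table.sample_meta.loc[sid].to_dict()
            meta["injection_order"] = idx
        new_meta[sid] = meta

    values = pd.DataFrame(new_values).T
    values.columns = table.values.columns
    sample_meta = pd.DataFrame(new_meta).T
    sample_meta["injection_order"] = sample_meta["injection_order"].astype(int)
    if drift is not None:
        factors = np.array([float(drift(i)) for i in sample_meta["injection_order"]])
        values = values.mul(factors, axis=0)
    return MetaboliteTable(values, sample_meta, table.metabolite_meta.copy())
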