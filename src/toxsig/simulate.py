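"""Synthetic two-tissue dose-response microarray study generator.

Emulates the structure of a rat hepatotoxicity study: a training arm
(4 rats/group at 0, 150, 1500, 2500 mg/kg) and a test arm (6 rats/group at
0, 150, 1500, 2000 mg/kg), each animal sampled at one time point (6 h or
24 h), both liver and whole blood profiled, and each animal×tissue
hybridized on a dye-swap pair of two-color arrays. Values are log2 ratios
of treated vs. the time-matched control average, so vehicle animals have
expectation zero.

Planted genes follow tissue × dose-class template shapes with per-gene
loading spread and i.i.d. Gaussian array noise; background genes are pure
noise. A serum-ALT phenotype is simulated with responder heterogeneity:
a toxic-dose animal may fail to develop injury (a non-responder), in which
case both its ALT and — when anchoring is on — its expression follow the
subtoxic level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .groups import SUBTOXIC_CLASS, TOXIC_CLASS, VEHICLE_CLASS, dose_class

__all__ = [
    "StudyDesign",
    "PatternTemplate",
    "SyntheticTruth",
    "generate_design",
    "generate_expression",
    "generate_alt",
    "simulate_study",
    "default_templates",
    "coregulation_templates",
]

TISSUES = ("blood", "liver")
ARM_DOSES = {
    "training": (0.0, 150.0, 1500.0, 2500.0),
    "test": (0.0, 150.0, 1500.0, 2000.0),
}
ARM_RATS = {"training": 4, "test": 6}

#: ALT (U/L) generative ranges. Healthy serum ALT sits in the tens of U/L
#: (subtoxic group means around 47–76); overt hepatocellular injury spans
#: roughly 200–12,000 U/L with heavy right skew, modeled log-uniform.
NO_INJURY_BOUNDS = (30.0, 100.0)
NO_INJURY_MEAN, NO_INJURY_SD = 62.0, 13.0
INJURY_BOUNDS = (200.0, 12000.0)


@dataclass(frozen=True)
class StudyDesign:
    """One arm × time-point cell of the study layout."""

    arm: str
    time_point_h: int
    rats_per_group: int
    dose_groups: tuple  # mg/kg, including 0 for vehicle
    n_vehicle: int
    tissues: tuple = TISSUES
    arrays_per_animal: int = 2  # dye-swap pair

    def __post_init__(self):
        if self.arm not in ARM_DOSES:
            raise ValueError(f"unknown arm {self.arm!r}; expected 'training' or 'test'")
        if self.time_point_h not in (6, 24):
            raise ValueError(f"unknown time point {self.time_point_h}; expected 6 or 24")


@dataclass(frozen=True)
class PatternTemplate:
    """A planted co-expression shape.

    ``means`` maps (tissue, dose_class) to the template's mean log2 ratio in
    that cell; missing cells (and vehicle) default to 0. Per-gene loadings
    are uniform scalar multipliers of the whole shape so planted genes
    correlate with, but do not duplicate, the template.
    """

    template_id: str
    means: dict  # (tissue, dose_class) -> float
    n_genes: int = 200
    loading_range: tuple = (0.7, 1.3)
    noise_sd: float | None = None  # None -> generator-wide default

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("template needs n_genes >= 1")
        if all(v == 0 for v in self.means.values()):
            raise ValueError(f"template {self.template_id!r} is all-zero; use background genes")

    def cell_mean(self, tissue: str, dclass: str) -> float:
        return float(self.means.get((tissue, dclass), 0.0))


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated study, used as the oracle in tests."""

    templates: list
    gene_template: pd.Series  # gene_id -> template_id or "" for background
    loadings: pd.Series  # gene_id -> scalar loading (1.0 for background)
    alt: pd.DataFrame | None = None  # animal_id, alt_u_per_l, responder
    effective_class: dict = field(default_factory=dict)

    def labels(self) -> pd.Series:
        """Template membership as categorical labels, background = ''."""
        return self.gene_template


def generate_design(arm: str, time_point_h: int, seed: int = 0, n_vehicle: int | None = None):
    """Lay out animals and arrays for one arm × time point.

    Returns the :class:`StudyDesign` and a sample-metadata table with one row
    per array: array_id, animal_id, tissue, dose_mg_kg, dose_class, time_h,
    dye ∈ {forward, swap}. The layout is deterministic; ``seed`` is accepted
    for interface symmetry with the stochastic generators.
    """
    if arm not in ARM_DOSES:
        raise ValueError(f"unknown arm {arm!r}; expected 'training' or 'test'")
    if time_point_h not in (6, 24):
        raise ValueError(f"unknown time point {time_point_h!r}; expected 6 or 24")
    rats = ARM_RATS[arm]
    if n_vehicle is None:
        n_vehicle = rats
    design = StudyDesign(arm, time_point_h, rats, ARM_DOSES[arm], n_vehicle)

    rows = []
    for dose in design.dose_groups:
        dclass = dose_class(dose)
        n = n_vehicle if dclass == VEHICLE_CLASS else rats
        for r in range(1, n + 1):
            animal = f"{arm[:2]}{time_point_h}h_d{int(dose)}_r{r}"
            for tissue in design.tissues:
                for k, dye in enumerate(("forward", "swap")):
                    rows.append(
                        {
                            "array_id": f"{animal}_{tissue}_a{k + 1}",
                            "animal_id": animal,
                            "tissue": tissue,
                            "dose_mg_kg": dose,
                            "dose_class": dclass,
                            "time_h": time_point_h,
                            "dye": dye,
                        }
                    )
    return design, pd.DataFrame(rows)


def _truncnorm_rvs(lo, hi, mean, sd, size, rng):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return sps.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_alt(
    metadata: pd.DataFrame,
    responder_fraction: float = 1.0,
    seed: int = 0,
    nonresponders: list | None = None,
) -> pd.DataFrame:
    """Simulate serum ALT (U/L) per animal with responder heterogeneity.

    Vehicle, subtoxic, and all 6-h animals draw from a truncated-normal
    no-injury distribution on (30, 100). Toxic-dose animals are responders
    with probability ``responder_fraction`` (or exactly the animals named in
    ``nonresponders`` are non-responders); at 24 h responders draw ALT
    log-uniformly from (200, 12000), non-responders from the no-injury
    distribution. Responder flags are drawn at 6 h too — they drive
    expression anchoring even though injury is not yet measurable.
    """
    if not 0.0 <= responder_fraction <= 1.0:
        raise ValueError("responder_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    animals = metadata.drop_duplicates("animal_id")[
        ["animal_id", "dose_class", "time_h"]
    ].reset_index(drop=True)

    toxic = animals["dose_class"] == TOXIC_CLASS
    if nonresponders is not None:
        unknown = set(nonresponders) - set(animals["animal_id"])
        if unknown:
            raise ValueError(f"nonresponders not in design: {sorted(unknown)}")
        responder = ~animals["animal_id"].isin(nonresponders)
        if (~responder & ~toxic).any():
            raise ValueError("only toxic-dose animals can be non-responders")
    else:
        draw = rng.random(len(animals)) < responder_fraction
        responder = pd.Series(True, index=animals.index)
        responder[toxic] = draw[toxic]

    n = len(animals)
    alt = _truncnorm_rvs(*NO_INJURY_BOUNDS, NO_INJURY_MEAN, NO_INJURY_SD, n, rng)
    injured = toxic & responder & (animals["time_h"] == 24)
    k = int(injured.sum())
    if k:
        lo, hi = np.log(INJURY_BOUNDS[0]), np.log(INJURY_BOUNDS[1])
        alt[injured.to_numpy()] = np.exp(rng.uniform(lo, hi, size=k))
    out = animals.copy()
    out["alt_u_per_l"] = alt
    out["responder"] = responder.to_numpy()
    return out


def generate_expression(
    metadata: pd.DataFrame,
    templates: list,
    n_background_genes: int = 0,
    noise_sd: float = 0.2,
    seed: int = 0,
    effective_class: dict | None = None,
):
    """Simulate the genes × arrays log2-ratio matrix.

    Each planted gene's biological value in an animal×tissue is
    ``loading × template mean`` for that tissue and the animal's *effective*
    dose class (``effective_class`` overrides, e.g. mapping a non-responder
    toxic animal to the subtoxic level). Every array observes that value plus
    i.i.d. Gaussian noise; arrays whose dye orientation is ``swap`` store the
    measurement sign-flipped. Background genes are pure noise.

    Returns the expression DataFrame (genes × array_ids, column order equal
    to ``metadata`` row order) and the :class:`SyntheticTruth`.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    if not templates and n_background_genes <= 0:
        raise ValueError("need at least one template or background genes")
    ids = [t.template_id for t in templates]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate template ids")

    rng = np.random.default_rng(seed)
    eff = dict(effective_class or {})
    meta = metadata.reset_index(drop=True)

    # per-array effective dose class
    eff_class = np.array(
        [eff.get(a, d) for a, d in zip(meta["animal_id"], meta["dose_class"])]
    )
    tissue = meta["tissue"].to_numpy()
    sign = np.where(meta["dye"].to_numpy() == "swap", -1.0, 1.0)
    n_arrays = len(meta)

    gene_ids, template_of, loadings, rows = [], [], [], []
    for t in templates:
        lo, hi = t.loading_range
        lam = rng.uniform(lo, hi, size=t.n_genes)
        sd = noise_sd if t.noise_sd is None else t.noise_sd
        if sd <= 0:
            raise ValueError(f"template {t.template_id!r} noise_sd must be positive")
        cell = np.array([t.cell_mean(ti, dc) for ti, dc in zip(tissue, eff_class)])
        bio = lam[:, None] * cell[None, :]
        rows.append(sign[None, :] * (bio + rng.normal(0.0, sd, size=(t.n_genes, n_arrays))))
        gene_ids += [f"{t.template_id}_g{k + 1}" for k in range(t.n_genes)]
        template_of += [t.template_id] * t.n_genes
        loadings += list(lam)
    if n_background_genes:
        rows.append(
            sign[None, :] * rng.normal(0.0, noise_sd, size=(n_background_genes, n_arrays))
        )
        gene_ids += [f"bg_g{k + 1}" for k in range(n_background_genes)]
        template_of += [""] * n_background_genes
        loadings += [1.0] * n_background_genes

    expr = pd.DataFrame(np.vstack(rows), index=gene_ids, columns=meta["array_id"])
    expr.index.name = "gene_id"
    truth = SyntheticTruth(
        templates=list(templates),
        gene_template=pd.Series(template_of, index=gene_ids, name="template_id"),
        loadings=pd.Series(loadings, index=gene_ids, name="loading"),
        effective_class=eff,
    )
    return expr, truth


def default_templates(n_genes: int = 200) -> list:
    """Six well-separated planted shapes spanning the study's pattern variety.

    Three contrast directions and their negations, mutually orthogonal under
    the study's weighted column expansion: dose-dependent change shared by
    both tissues (the co-regulated shape, down and up), a dose-independent
    opposite-direction tissue contrast, and a tissue × dose interaction.
    """
    b, l = TISSUES
    s, t = SUBTOXIC_CLASS, TOXIC_CLASS

    def tpl(tid, bs, bt, ls, lt):
        return PatternTemplate(
            tid, {(b, s): bs, (b, t): bt, (l, s): ls, (l, t): lt}, n_genes=n_genes
        )

    return [
        tpl("down_both_dose", -0.6, -1.6, -0.6, -1.6),
        tpl("up_both_dose", 0.6, 1.6, 0.6, 1.6),
        tpl("blood_up_liver_down", 1.0, 1.0, -1.0, -1.0),
        tpl("blood_down_liver_up", -1.0, -1.0, 1.0, 1.0),
        tpl("interaction_a", 1.2, -0.6, -1.2, 0.6),
        tpl("interaction_b", -1.2, 0.6, 1.2, -0.6),
    ]


def coregulation_templates(n_genes: int = 100) -> list:
    """The four qualitative cross-tissue shapes used to test co-regulation flagging.

    Down in both tissues to the same extent; down in both with blood more
    affected; up in liver only; opposite directions in the two tissues. Only
    the first two count as co-regulated.
    """
    b, l = TISSUES
    s, t = SUBTOXIC_CLASS, TOXIC_CLASS

    def tpl(tid, bs, bt, ls, lt):
        return PatternTemplate(
            tid, {(b, s): bs, (b, t): bt, (l, s): ls, (l, t): lt}, n_genes=n_genes
        )

    return [
        tpl("down_both_equal", -0.6, -1.4, -0.6, -1.4),
        tpl("down_both_blood_more", -1.0, -2.0, -0.5, -1.0),
        tpl("up_liver_only", 0.0, 0.0, 0.8, 1.6),
        tpl("opposite_direction", 0.5, 1.0, -0.5, -1.0),
    ]


def simulate_study(
    arm: str,
    time_point_h: int,
    templates: list | None = None,
    n_background_genes: int = 4000,
    noise_sd: float = 0.2,
    responder_fraction: float = 1.0,
    seed: int = 0,
    n_vehicle: int | None = None,
    nonresponders: list | None = None,
    anchor_to_responders: bool = True,
):
    """Generate a complete arm × time-point dataset.

    With ``anchor_to_responders`` (the default), toxic-dose non-responders
    express the subtoxic template level — the expression phenotype tracks
    injury rather than administered dose. Returns a dict with keys
    ``design, metadata, expression, alt, truth``.
    """
    if templates is None:
        templates = default_templates()
    design, metadata = generate_design(arm, time_point_h, seed=seed, n_vehicle=n_vehicle)
    alt = generate_alt(
        metadata, responder_fraction=responder_fraction, seed=seed + 1, nonresponders=nonresponders
    )
    eff = None
    if anchor_to_responders:
        nonresp = alt.loc[~alt["responder"], "animal_id"]
        eff = {a: SUBTOXIC_CLASS for a in nonresp}
    expr, truth = generate_expression(
        metadata,
        templates,
        n_background_genes=n_background_genes,
        noise_sd=noise_sd,
        seed=seed + 2,
        effective_class=eff,
    )
    truth.alt = alt
    return {
        "design": design,
        "metadata": metadata,
        "expression": expr,
        "alt": alt,
        "truth": truth,
    }
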