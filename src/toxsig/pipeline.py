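"""End-to-end stage orchestration shared by the CLI and scripted analyses.

``run_extract`` mirrors the training-arm analysis: orientation-correct the
arrays (keeping both arrays of a rat as separate profile columns), align,
extract patterns over the tissue × dose-class structure, categorize genes,
and flag the patterns co-regulated across tissues. ``run_classify`` mirrors
the test-arm validation: dye-swap-average per animal, build the signature
matrix per tissue, and report the two-cut separation under dose-class and
ALT-injury labelings.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import (
    SignatureSeparator,
    build_signature_matrix,
    injury_labels,
    pca_2d,
    separation_report,
)
from .extract import ExtractionParams, extract_patterns, flag_coregulated
from .groups import VEHICLE_CLASS, GroupStructure
from .preprocess import dye_swap_correct, orient_forward, reference_align

__all__ = ["run_extract", "run_classify", "signature_table"]


def run_extract(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    params: ExtractionParams | None = None,
    align: bool = False,
):
    """Pattern extraction on per-array profiles (both arrays per rat kept).

    Returns a dict with the fitted extractor, the per-column metadata of the
    analyzed (non-vehicle) columns, the assignments table restricted to
    extracted patterns, and the per-pattern co-regulation flags.
    """
    params = params or ExtractionParams()
    meta = metadata.reset_index(drop=True)
    fwd = orient_forward(expr, meta)
    fwd = reference_align(fwd, enabled=align)

    keep = GroupStructure.column_mask(meta, exclude_vehicle=True)
    cols_meta = meta[keep].reset_index(drop=True)
    X = fwd.loc[:, cols_meta["array_id"]]
    groups = GroupStructure.from_metadata(meta, exclude_vehicle=True)

    est = extract_patterns(X, groups, params)
    for p in est.patterns_:
        flag_coregulated(
            p,
            cols_meta,
            s_magnitude=params.s_magnitude,
            agreement_r=params.agreement_r,
            strict_eq1_sign=params.strict_eq1_sign,
        )
    return {
        "extractor": est,
        "params": params,
        "column_meta": cols_meta,
        "groups": groups,
        "patterns": est.patterns_,
        "assignments": est.assignments_,
        "r_star": est.r_star_,
    }


def signature_table(result: dict, coregulated_only: bool = True) -> pd.DataFrame:
    """Assigned genes (gene_id, pattern_id, direction) of an extract run.

    ``coregulated_only`` keeps genes of cross-tissue co-regulated patterns —
    the signature the validation stage evaluates.
    """
    asg = result["assignments"]
    keep_ids = {
        p.pattern_id
        for p in result["patterns"]
        if (p.coregulated or not coregulated_only)
    }
    out = asg[asg["assigned"] & asg["pattern_id"].isin(keep_ids)].copy()
    out["direction"] = np.where(out["S"] > 0, "up", "down")
    return out[["gene_id", "pattern_id", "direction", "r", "S", "SNR"]].reset_index(drop=True)


def run_classify(
    expr: pd.DataFrame,
    metadata: pd.DataFrame,
    signature_genes,
    alt: pd.DataFrame | None = None,
    tissues=("liver", "blood"),
    label_schemes=("dose", "injury"),
):
    """Evaluate a signature on an animal set, per tissue and label scheme.

    Dose labels contrast subtoxic vs. toxic administered dose; injury labels
    come from serum ALT (indeterminate animals are excluded from scoring).
    Returns nested dict: tissue -> scheme -> {report, pca, separator, matrix}.
    """
    corrected, col_meta = dye_swap_correct(expr, metadata)
    animals = metadata.drop_duplicates("animal_id").set_index("animal_id")
    dose_lab = animals["dose_class"]

    schemes = {}
    if "dose" in label_schemes:
        schemes["dose"] = dose_lab[dose_lab != VEHICLE_CLASS]
    if "injury" in label_schemes:
        if alt is None:
            raise ValueError("injury labeling needs an ALT table")
        inj = injury_labels(alt)
        schemes["injury"] = inj[(inj != "indeterminate") & (dose_lab.reindex(inj.index) != VEHICLE_CLASS)]

    results = {}
    for tissue in tissues:
        results[tissue] = {}
        for name, labels in schemes.items():
            sig = build_signature_matrix(corrected, col_meta, signature_genes, tissue, labels)
            sep = SignatureSeparator().fit(sig.values)
            report = separation_report(sep.labels_, sig.labels)
            results[tissue][name] = {
                "matrix": sig,
                "separator": sep,
                "pca": sep.pca_coords_,
                "report": report,
            }
    return results
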