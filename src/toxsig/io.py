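"""Tab-delimited and JSON readers/writers for the pipeline's file dialects.

All tables are UTF-8 TSV. Expression files have genes as rows and a header
row of array (or animal×tissue) ids; the gene-id column is named gene_id.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .simulate import PatternTemplate, SyntheticTruth

__all__ = [
    "read_expression",
    "write_expression",
    "read_samples",
    "write_samples",
    "read_alt",
    "write_alt",
    "read_truth",
    "write_truth",
]


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.rename_axis("gene_id").to_csv(path, sep="\t")


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_samples(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_samples(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_alt(alt: pd.DataFrame, path) -> None:
    alt.to_csv(path, sep="\t", index=False)


def read_alt(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "templates": [
            {
                "template_id": t.template_id,
                "means": [[ti, dc, v] for (ti, dc), v in sorted(t.means.items())],
                "n_genes": t.n_genes,
                "loading_range": list(t.loading_range),
                "noise_sd": t.noise_sd,
            }
            for t in truth.templates
        ],
        "gene_template": truth.gene_template.to_dict(),
        "loadings": truth.loadings.to_dict(),
        "effective_class": truth.effective_class,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text())
    templates = [
        PatternTemplate(
            template_id=t["template_id"],
            means={(ti, dc): v for ti, dc, v in t["means"]},
            n_genes=t["n_genes"],
            loading_range=tuple(t["loading_range"]),
            noise_sd=t["noise_sd"],
        )
        for t in payload["templates"]
    ]
    return SyntheticTruth(
        templates=templates,
        gene_template=pd.Series(payload["gene_template"], name="template_id"),
        loadings=pd.Series(payload["loadings"], name="loading"),
        effective_class=payload.get("effective_class", {}),
    )
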