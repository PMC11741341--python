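"""Plain-text readers and writers for the pipeline's tables.

Formats:
* ReporterMatrix — TSV with columns ``protein_id``, ``n_unique_peptides``,
  then one column per TMT channel; empty cells are missing values.
* ImpurityMatrix — square CSV with a channel header row/column.
* StudyDesign — JSON with ``channels`` (channel -> {condition, replicate})
  and ``reference_condition``.
* RatioTable / DiffTestTable / FPR curve / HitTable — TSV.
* Control gene lists — one gene per line.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .quant import ImpurityMatrix, RatioTable, ReporterMatrix, StudyDesign

__all__ = [
    "read_reporter_tsv", "write_reporter_tsv",
    "read_impurity_csv", "write_impurity_csv",
    "read_design_json", "write_design_json",
    "write_ratio_tsv", "read_gene_list", "write_gene_list",
]


def write_reporter_tsv(m: ReporterMatrix, path) -> None:
    df = m.intensities.copy()
    df.insert(0, "n_unique_peptides", m.n_unique_peptides)
    df.to_csv(path, sep="\t", index_label="protein_id")


def read_reporter_tsv(path) -> ReporterMatrix:
    df = pd.read_csv(path, sep="\t", index_col="protein_id")
    peptides = df.pop("n_unique_peptides")
    return ReporterMatrix(df.astype(float), peptides.astype(int))


def write_impurity_csv(m: ImpurityMatrix, path) -> None:
    names = list(m.channel_names) if m.channel_names else [
        f"ch{i}" for i in range(m.n_channels)
    ]
    pd.DataFrame(m.values, index=names, columns=names).to_csv(path)


def read_impurity_csv(path) -> ImpurityMatrix:
    df = pd.read_csv(path, index_col=0)
    return ImpurityMatrix(df.to_numpy(dtype=float), channel_names=tuple(df.columns))


def write_design_json(design: StudyDesign, path) -> None:
    payload = {
        "reference_condition": design.reference_condition,
        "channels": {
            ch: {
                "condition": design.channel_to_condition[ch],
                "replicate": design.channel_to_replicate[ch],
            }
            for ch in design.channels
        },
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_design_json(path) -> StudyDesign:
    payload = json.loads(Path(path).read_text())
    chans = payload["channels"]
    return StudyDesign(
        channel_to_condition={ch: v["condition"] for ch, v in chans.items()},
        channel_to_replicate={ch: int(v["replicate"]) for ch, v in chans.items()},
        reference_condition=payload["reference_condition"],
    )


def write_ratio_tsv(r: RatioTable, path) -> None:
    r.ratios.to_csv(path, sep="\t", index_label="protein_id")


def read_gene_list(path) -> list[str]:
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip()]


def write_gene_list(genes, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
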