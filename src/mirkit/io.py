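"""Readers and writers for the plain-text dialects the pipeline consumes.

Cohort counts travel as TSV (``cohort_id, donor_class, sv_class,
signature, count``; ``NA`` marks unknown sub-splits), qPCR plates as CSV
(``well,target,Cq,efficiency``; empty or ``NA`` Cq marks a censored
no-amplification well), and scenario/run configuration as YAML or JSON.
"""

from __future__ import annotations

import json
import math
from typing import Mapping

import pandas as pd
import yaml

from .model import (
    ClassDistribution,
    Pathway,
    RecombinantClass,
    RepairScenario,
    Segregation,
)
from .quant import Measurement, QPCRRun

__all__ = [
    "read_cohort_tsv",
    "write_cohort_tsv",
    "read_qpcr_csv",
    "write_qpcr_csv",
    "read_scenario",
    "write_distribution_tsv",
]

_COHORT_COLUMNS = ["cohort_id", "donor_class", "sv_class", "signature", "count"]


def read_cohort_tsv(path) -> dict[str, dict[RecombinantClass, int]]:
    """Read cohort counts; rows with NA class fields are skipped.

    Returns ``{cohort_id: {RecombinantClass: count}}``.  Rows whose donor
    class, SV class or signature is ``NA`` encode marginals with unknown
    sub-splits and are not representable as a full class, so they are
    dropped here; use pandas directly if the marginal rows are needed.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(_COHORT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"cohort TSV missing columns: {sorted(missing)}")
    out: dict[str, dict[RecombinantClass, int]] = {}
    for _, row in df.iterrows():
        if any(
            pd.isna(row[c]) or str(row[c]).upper() == "NA"
            for c in ("donor_class", "sv_class", "signature")
        ):
            continue
        cls = RecombinantClass(
            row["donor_class"], int(row["sv_class"]), row["signature"]
        )
        cohort = out.setdefault(str(row["cohort_id"]), {})
        cohort[cls] = cohort.get(cls, 0) + int(row["count"])
    return out


def write_cohort_tsv(
    cohorts: Mapping[str, Mapping[RecombinantClass, int]], path
) -> None:
    rows = [
        {
            "cohort_id": cid,
            "donor_class": cls.donor_class.value,
            "sv_class": cls.sv_class,
            "signature": cls.signature.value,
            "count": int(n),
        }
        for cid, counts in cohorts.items()
        for cls, n in sorted(counts.items())
    ]
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_qpcr_csv(
    path,
    genomes_per_reaction: float = 1e5,
    dsb_cut_fraction: float = 0.99,
) -> QPCRRun:
    """Read a qPCR plate CSV (``well,target,Cq,efficiency``)."""
    df = pd.read_csv(path)
    required = {"well", "target", "Cq"}
    if not required <= set(df.columns):
        raise ValueError(f"qPCR CSV requires columns {sorted(required)}")
    if "efficiency" not in df.columns:
        df["efficiency"] = 2.0
    wells = []
    for _, row in df.iterrows():
        cq = row["Cq"]
        cq = float("nan") if pd.isna(cq) or str(cq).upper() == "NA" else float(cq)
        wells.append(
            Measurement(
                well=str(row["well"]),
                target=str(row["target"]),
                cq=cq,
                efficiency=float(row["efficiency"]),
            )
        )
    return QPCRRun(
        measurements=tuple(wells),
        genomes_per_reaction=genomes_per_reaction,
        dsb_cut_fraction=dsb_cut_fraction,
    )


def write_qpcr_csv(run: QPCRRun, path) -> None:
    rows = [
        {
            "well": m.well,
            "target": m.target,
            "Cq": "" if math.isnan(m.cq) else m.cq,
            "efficiency": m.efficiency,
        }
        for m in run.measurements
    ]
    pd.DataFrame(rows, columns=["well", "target", "Cq", "efficiency"]).to_csv(
        path, index=False
    )


def read_scenario(path) -> RepairScenario:
    """Read a repair scenario from YAML or JSON."""
    with open(path) as fh:
        text = fh.read()
    data = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    )
    if not isinstance(data, dict):
        raise ValueError("scenario file must contain a mapping")
    kwargs = {}
    if "pathway" in data:
        kwargs["pathway"] = Pathway(data["pathway"])
    if "segregation" in data:
        kwargs["segregation"] = Segregation(data["segregation"])
    for key in (
        "p_internal_repair",
        "displacement_synthesis",
        "mir2_min_flank_bp",
        "p_terminal_retention",
    ):
        if key in data:
            kwargs[key] = data[key]
    return RepairScenario(**kwargs)


def write_distribution_tsv(dist: ClassDistribution, path) -> None:
    rows = [
        {
            "class": cls.label,
            "donor_class": cls.donor_class.value,
            "sv_class": cls.sv_class,
            "signature": cls.signature.value,
            "probability": p,
        }
        for cls, p in sorted(dist.items())
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
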