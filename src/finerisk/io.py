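"""File formats: COJO-style ``.ma`` summary statistics, dosage TSV (with
SNV-metadata sidecar), VCF dosage (``DS`` FORMAT field), weight-panel and
score TSVs, rate CSVs, and selection/report outputs.

All tabular text formats round-trip (``write . read == id`` on valid
files).  Coordinates are 1-based in files (VCF convention) and 0-based
half-open internally.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import DosageMatrix, SummaryStatSet, WeightPanel
from .errors import ParseError
from .synthio import expand_rate_table

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


# ---------------------------------------------------------------------------
# COJO .ma summary statistics


def read_ma(path, study: str | None = None) -> SummaryStatSet:
    """Read whitespace-delimited ``SNP A1 A2 freq b se p N`` summary stats.

    Domain violations (se <= 0, p outside (0, 1], freq outside (0, 1),
    identical alleles) raise :class:`ParseError` naming the line.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().split()
        if header != MA_COLUMNS:
            raise ParseError(f"expected header {' '.join(MA_COLUMNS)!r}, got {' '.join(header)!r}",
                             path=path, line=1)
        rows = []
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) != 8:
                raise ParseError(f"expected 8 fields, got {len(parts)}", path=path, line=lineno)
            snp, a1, a2 = parts[0], parts[1], parts[2]
            try:
                freq, b, se, p, n = (float(x) for x in parts[3:])
            except ValueError as exc:
                raise ParseError(f"non-numeric field: {exc}", path=path, line=lineno) from exc
            if a1 == a2:
                raise ParseError(f"identical alleles {a1!r} for {snp}", path=path, line=lineno)
            if se <= 0:
                raise ParseError(f"se must be > 0 (got {se})", path=path, line=lineno)
            if not 0.0 < p <= 1.0:
                raise ParseError(f"p must be in (0, 1] (got {p})", path=path, line=lineno)
            if not 0.0 < freq < 1.0:
                raise ParseError(f"freq must be in (0, 1) (got {freq})", path=path, line=lineno)
            rows.append({"snv": snp, "a1": a1, "a2": a2, "freq": freq,
                         "b": b, "se": se, "p": p, "n": n})
    table = pd.DataFrame(rows, columns=["snv", "a1", "a2", "freq", "b", "se", "p", "n"])
    table = table.set_index("snv")
    if not table.index.is_unique:
        dup = table.index[table.index.duplicated()][0]
        raise ParseError(f"duplicate SNV id {dup!r}", path=path)
    return SummaryStatSet(study or path.stem, table)


def write_ma(sset: SummaryStatSet, path) -> None:
    out = sset.table.reset_index()
    out.columns = MA_COLUMNS
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# dosage matrices


def write_dosage_tsv(panel: DosageMatrix, matrix_path, snv_path) -> None:
    """Individuals x SNVs dosage TSV plus an SNV-metadata sidecar (1-based pos)."""
    df = pd.DataFrame(panel.dosages, index=panel.samples, columns=panel.snvs.index)
    df.index.name = "individual"
    df.to_csv(matrix_path, sep="\t", float_format="%.6g")
    meta = panel.snvs.copy()
    meta["pos"] = meta["pos"] + 1
    meta.to_csv(snv_path, sep="\t")


def read_dosage_tsv(matrix_path, snv_path) -> DosageMatrix:
    df = pd.read_csv(matrix_path, sep="\t", index_col=0)
    meta = pd.read_csv(snv_path, sep="\t", index_col=0, dtype={"chrom": str})
    meta["pos"] = meta["pos"] - 1
    if list(df.columns) != list(meta.index):
        raise ParseError("dosage matrix columns disagree with SNV metadata", path=matrix_path)
    dosages = df.to_numpy(dtype=float)
    if dosages.size and (dosages.min() < 0 or dosages.max() > 2):
        raise ParseError("dosages must lie in [0, 2]", path=matrix_path)
    return DosageMatrix(df.index, meta, dosages)


def read_vcf_dosages(path, require_ds: bool = True) -> DosageMatrix:
    """Dosage matrix from a VCF with a per-genotype ``DS`` FORMAT field.

    Falls back to genotype allele counts when ``DS`` is absent and
    ``require_ds`` is False.  The VCF ALT allele is taken as the effect
    allele (the allele dosage counts).
    """
    from cyvcf2 import VCF  # deferred: optional heavyweight import

    vcf = VCF(str(path))
    samples = pd.Index(vcf.samples, name="individual")
    meta_rows, cols = [], []
    for var in vcf:
        if var.ID is None:
            raise ParseError("VCF records must carry SNV ids", path=path)
        try:
            ds = var.format("DS")
        except KeyError:
            ds = None
        if ds is not None:
            col = np.asarray(ds, dtype=float).reshape(len(samples))
        elif require_ds:
            raise ParseError(f"record {var.ID} lacks the DS FORMAT field", path=path)
        else:
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            gt = np.asarray(var.gt_types)
            col = np.where(gt == 2, np.nan, np.where(gt == 3, 2.0, gt.astype(float)))
        meta_rows.append({"snv": var.ID, "chrom": str(var.CHROM), "pos": var.POS - 1,
                          "effect_allele": var.ALT[0], "other_allele": var.REF})
        cols.append(col)
    meta = pd.DataFrame(meta_rows).set_index("snv")
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return DosageMatrix(samples, meta, dosages)


# ---------------------------------------------------------------------------
# panels, scores, cohorts, rates, selections, reports


def write_weight_panel(panel: WeightPanel, path) -> None:
    out = panel.table.copy()
    out["tier"] = panel.tier
    out["threshold"] = "" if panel.threshold is None else repr(panel.threshold)
    out["source"] = panel.source or ""
    out.index.name = "snv"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_weight_panel(path) -> WeightPanel:
    df = pd.read_csv(path, sep="\t", index_col=0, keep_default_na=False, na_values=[""])
    thr = df["threshold"].iloc[0] if len(df) else None
    thr = None if (thr is None or (isinstance(thr, float) and np.isnan(thr))) else float(thr)
    tier = df["tier"].iloc[0] if len(df) else "external"
    source = df["source"].iloc[0] if len(df) and isinstance(df["source"].iloc[0], str) else None
    cols = [c for c in ("effect_allele", "weight", "freq") if c in df.columns]
    return WeightPanel(df[cols].copy(), tier=tier, threshold=thr, source=source)


def write_scores(scores: pd.DataFrame, path) -> None:
    out = scores.copy()
    out.index.name = "individual"
    out.to_csv(path, sep="\t", float_format="%.10g", na_rep="NA")


def read_scores(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_cohort_tsv(cohort: pd.DataFrame, path) -> None:
    cohort.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


def read_cohort_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])


def write_rate_table(rates: pd.DataFrame, path) -> None:
    rates.to_csv(path, index=False, float_format="%.10g")


def read_rate_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"age", "incidence", "mortality"}
    if not required.issubset(df.columns):
        raise ParseError(f"rate table needs columns {sorted(required)}", path=path)
    if (df[["incidence", "mortality"]].to_numpy() < 0).any():
        raise ParseError("rates must be >= 0", path=path)
    if not df["age"].is_monotonic_increasing:
        raise ParseError("age bins must be sorted", path=path)
    return expand_rate_table(df)


_SELECTION_COLUMNS = ["locus", "eligible", "snv", "order", "joint_b", "joint_se",
                      "joint_p", "threshold", "lead_b", "lead_p"]


def write_selection_tsv(selections: list, path) -> None:
    rows = []
    for sel in selections:
        if sel.eligible:
            for snv, row in sel.joint.iterrows():
                rows.append({"locus": sel.locus_id, "eligible": True, "snv": snv,
                             "order": int(row["order"]), "joint_b": row["b"],
                             "joint_se": row["se"], "joint_p": row["p"],
                             "threshold": sel.threshold,
                             "lead_b": sel.lead_b, "lead_p": sel.lead_p})
        else:
            rows.append({"locus": sel.locus_id, "eligible": False, "snv": sel.lead_snv,
                         "order": -1, "joint_b": np.nan, "joint_se": np.nan,
                         "joint_p": np.nan, "threshold": sel.threshold,
                         "lead_b": sel.lead_b, "lead_p": sel.lead_p})
    pd.DataFrame(rows, columns=_SELECTION_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_selection_tsv(path) -> list:
    """Rebuild :class:`~finerisk.containers.SelectionResult` objects.

    Member lists are not persisted; only what panel construction needs
    (selection order, joint estimates, eligibility, lead statistics)
    round-trips.
    """
    from .containers import SelectionResult

    df = pd.read_csv(path, sep="\t")
    out = []
    for locus, grp in df.groupby("locus", sort=False):
        thr = float(grp["threshold"].iloc[0])
        if bool(grp["eligible"].iloc[0]):
            grp = grp.sort_values("order")
            joint = pd.DataFrame(
                {"b": grp["joint_b"].to_numpy(), "se": grp["joint_se"].to_numpy(),
                 "p": grp["joint_p"].to_numpy(), "order": grp["order"].to_numpy()},
                index=pd.Index(grp["snv"], name="snv"),
            )
            out.append(SelectionResult(locus, True, list(joint.index), joint, thr,
                                       list(joint.index),
                                       lead_snv=str(grp["snv"].iloc[0]),
                                       lead_b=float(grp["lead_b"].iloc[0]),
                                       lead_p=float(grp["lead_p"].iloc[0])))
        else:
            row = grp.iloc[0]
            empty = pd.DataFrame(columns=["b", "se", "p", "order"],
                                 index=pd.Index([], name="snv"))
            out.append(SelectionResult(locus, False, [], empty, thr, [],
                                       lead_snv=str(row["snv"]),
                                       lead_b=float(row["lead_b"]),
                                       lead_p=float(row["lead_p"])))
    return out


def write_report_json(reports, path) -> None:
    payload = [r.to_dict() if hasattr(r, "to_dict") else r for r in reports]
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
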