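"""MRS metabolite QC filtering, tissue correction, and creatine ratios.

Operates on quantification tables (one row per metabolite estimate) with
spectral QC fields and voxel tissue fractions. Spectral fitting itself is
upstream; this module applies the exclusion rules and partial-volume
scaling, then expresses GABA/Glu as ratios to tissue-corrected total
creatine.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MetaboliteRecord",
    "QC_RULES",
    "qc_filter",
    "tissue_correct",
    "creatine_correct",
    "ratio_to_creatine",
    "metabolite_ratios",
]

REQUIRED_QC_FIELDS = ("crlb", "fwhm_hz", "snr")
TISSUE_FIELDS = ("gm", "wm", "csf")


@dataclass(frozen=True)
class MetaboliteRecord:
    """One quantified metabolite with QC fields and tissue fractions."""

    metabolite: str
    absolute: float
    crlb: float
    fwhm_hz: float
    snr: float
    gm: float
    wm: float
    csf: float

    def __post_init__(self) -> None:
        if abs(self.gm + self.wm + self.csf - 1.0) > 1e-6:
            raise ValueError("tissue fractions must sum to 1")
        if self.crlb < 0 or self.snr < 0:
            raise ValueError("crlb and snr must be non-negative")


def _qc_crlb(rec) -> bool:
    return rec["crlb"] > 50.0


def _qc_crlb_strict(rec) -> bool:
    return not (rec["crlb"] < 30.0)


def _qc_fwhm(rec) -> bool:
    return rec["fwhm_hz"] > 15.0


def _qc_snr(rec) -> bool:
    return rec["snr"] < 40.0


#: exclusion rules per mode; a record is excluded iff any rule fires
QC_RULES = {
    "default": {"crlb>50%": _qc_crlb, "fwhm>15Hz": _qc_fwhm, "snr<40": _qc_snr},
    "strict": {"crlb>=30%": _qc_crlb_strict, "fwhm>15Hz": _qc_fwhm, "snr<40": _qc_snr},
}


def qc_filter(
    records: pd.DataFrame, mode: str = "default"
) -> tuple[pd.DataFrame, list[dict]]:
    """Split a metabolite table into kept rows and an exclusion log.

    Default mode excludes on CRLB > 50%, FWHM > 15 Hz, or SNR < 40 (all
    strict inequalities); strict mode tightens the CRLB keep rule to < 30%.
    The log names every violated rule per excluded row.
    """
    if mode not in QC_RULES:
        raise ValueError(f"unknown QC mode {mode!r}")
    missing = [f for f in REQUIRED_QC_FIELDS if f not in records.columns]
    if missing:
        raise ValueError(f"missing QC fields: {missing}")
    if records[list(REQUIRED_QC_FIELDS)].isna().any().any():
        raise ValueError("QC fields contain missing values")
    rules = QC_RULES[mode]
    exclusion_log: list[dict] = []
    keep = np.ones(len(records), dtype=bool)
    for pos, (idx, row) in enumerate(records.iterrows()):
        violated = [name for name, rule in rules.items() if rule(row)]
        if violated:
            keep[pos] = False
            entry = {"index": idx, "violated": violated}
            if "metabolite" in records.columns:
                entry["metabolite"] = row["metabolite"]
            exclusion_log.append(entry)
    return records.loc[keep], exclusion_log


def tissue_correct(record: MetaboliteRecord | pd.Series) -> tuple[float, float]:
    """Partial-volume correct a GM-resident metabolite (GABA/Glu).

    Divides the absolute estimate by the gray-matter fraction
    gm / (gm + wm + csf). Returns (corrected value, correction factor);
    factor >= 1 whenever gm <= total.
    """
    if isinstance(record, MetaboliteRecord):
        gm, wm, csf, absolute = record.gm, record.wm, record.csf, record.absolute
    else:
        gm, wm, csf, absolute = (float(record[k]) for k in ("gm", "wm", "csf", "absolute"))
    if gm <= 0:
        raise ValueError("gm fraction must be > 0 for GM correction")
    fraction = gm / (gm + wm + csf)
    factor = 1.0 / fraction
    return absolute * factor, factor


def creatine_correct(
    cr: MetaboliteRecord | pd.Series, pcr: MetaboliteRecord | pd.Series
) -> float:
    """Brain-volume correct total creatine (Cr + PCr).

    Divides the summed absolute estimates by (gm + wm) / (gm + wm + csf).
    """
    def _f(rec, name):
        return getattr(rec, name) if isinstance(rec, MetaboliteRecord) else float(rec[name])

    gm, wm, csf = _f(cr, "gm"), _f(cr, "wm"), _f(cr, "csf")
    if gm + wm <= 0:
        raise ValueError("gm + wm must be > 0 for creatine correction")
    fraction = (gm + wm) / (gm + wm + csf)
    return (_f(cr, "absolute") + _f(pcr, "absolute")) / fraction


def ratio_to_creatine(metab_corrected: float, cr_corrected: float) -> float:
    """Corrected metabolite expressed relative to corrected total creatine."""
    if cr_corrected <= 0:
        raise ValueError("total creatine must be > 0")
    return metab_corrected / cr_corrected


def metabolite_ratios(
    records: pd.DataFrame,
    metabolites: tuple[str, ...] = ("GABA", "Glu"),
    qc_mode: str = "default",
    apply_ratio: bool = True,
) -> tuple[pd.Series, list[dict]]:
    """Full per-voxel pipeline: QC -> tissue correction -> Cr ratio.

    ``records`` holds one voxel's table (one row per metabolite, including
    Cr and PCr). Returns a Series of '<met>_cr' ratios (or raw corrected
    concentrations if ``apply_ratio`` is False) plus the QC exclusion log.
    Metabolites removed by QC come back as NaN.
    """
    kept, log = qc_filter(records, mode=qc_mode)
    by_name = kept.set_index("metabolite")
    out: dict[str, float] = {}
    cr_corrected = None
    if apply_ratio:
        if not {"Cr", "PCr"}.issubset(by_name.index):
            raise ValueError("Cr and PCr rows required for creatine ratios")
        cr_corrected = creatine_correct(by_name.loc["Cr"], by_name.loc["PCr"])
    for met in metabolites:
        key = f"{met.lower()}_cr" if apply_ratio else met.lower()
        if met not in by_name.index:
            out[key] = np.nan
            continue
        corrected, _ = tissue_correct(by_name.loc[met])
        out[key] = (ratio_to_creatine(corrected, cr_corrected)
                    if apply_ratio else corrected)
    return pd.Series(out), log
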