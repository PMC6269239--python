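"""End-to-end analysis pipeline: validate -> ratios -> IVW -> Egger -> Q/Q'.

This is the one-call surface used by the command-line front end and the
worked examples; every step is also available individually from the
dedicated modules.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import pandas as pd

from . import estimators, heterogeneity
from .data_model import (
    EggerResult,
    InsufficientInstrumentsError,
    IvwResult,
    PleiotropyReport,
    SummaryDataSet,
)

__all__ = ["MRAnalysis", "analyze"]


@dataclass(frozen=True)
class MRAnalysis:
    """Bundled results of a full pleiotropy-aware MR analysis."""

    data: SummaryDataSet
    ivw: IvwResult
    egger: EggerResult | None
    report: PleiotropyReport | None
    egger_note: str | None = None
    removal: heterogeneity.OutlierRemovalResult | None = None

    def snp_table(self) -> pd.DataFrame:
        """Per-SNP contribution table with flags at both thresholds."""
        table = pd.DataFrame(
            {
                "snp": self.data.snp_id,
                "q_contrib": self.ivw.q_contributions,
            }
        )
        if self.egger is not None:
            qp = heterogeneity.rucker_q(self.data, self.egger)
            table["q_prime_contrib"] = qp.contributions
        if self.report is not None:
            table["flag_95"] = self.report.q_flags_uncorrected
            table["flag_bonf"] = self.report.q_flags_bonferroni
        return table

    def to_dict(self) -> dict:
        out: dict = {"m": self.data.m, "ivw": self.ivw.to_dict()}
        if self.egger is not None:
            out["egger"] = self.egger.to_dict()
        else:
            out["egger"] = None
            out["egger_note"] = self.egger_note
        if self.report is not None:
            out["pleiotropy"] = {
                "global_q_pvalue": self.report.global_q_pvalue,
                "global_q_prime_pvalue": self.report.global_q_prime_pvalue,
                "fwer": self.report.fwer,
                "threshold_uncorrected": self.report.threshold_uncorrected,
                "threshold_bonferroni": self.report.threshold_bonferroni,
                "outlier_ids": self.report.outlier_ids,
                "model_hint": self.report.model_hint,
                "q_minus_q_prime": self.report.q_minus_q_prime,
            }
        if self.removal is not None:
            out["outlier_removal"] = {
                "removed_ids": self.removal.removed_ids,
                "rounds": self.removal.rounds,
                "refit_ivw": self.removal.ivw.to_dict(),
                "refit_egger": None
                if self.removal.egger is None
                else self.removal.egger.to_dict(),
            }
        return out

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary_lines(self) -> list[str]:
        """Console block: Q, Q', their difference and the model hint."""
        ivw = self.ivw
        lines = [
            f"m = {self.data.m} SNPs",
            f"IVW estimate  {ivw.beta_ivw:+.6g}  (SE {ivw.se:.6g})",
            f"Cochran's Q   {ivw.q_stat:.6g}  df {ivw.q_df}  p {ivw.q_pvalue:.6g}",
        ]
        if self.egger is not None:
            eg = self.egger
            lines += [
                f"Egger slope   {eg.slope:+.6g}  (SE {eg.slope_se:.6g})",
                f"Egger intercept {eg.intercept:+.6g}  (SE {eg.intercept_se:.6g}"
                f", p {eg.intercept_pvalue:.6g})",
                f"Rucker's Q'   {eg.q_prime:.6g}  df {eg.q_prime_df}"
                f"  p {eg.q_prime_pvalue:.6g}",
                f"Q - Q'        {ivw.q_stat - eg.q_prime:.6g}",
            ]
        else:
            lines.append(f"MR-Egger      unavailable ({self.egger_note})")
        if self.report is not None:
            lines.append(
                f"Outliers (Bonferroni on Qj): "
                f"{self.report.outlier_ids or 'none'}"
            )
            lines.append(f"Model hint    {self.report.model_hint}")
        return lines


def analyze(
    data: SummaryDataSet,
    level: float = 0.05,
    fwer: float = 0.05,
    random_effects: bool = False,
    t_inference: bool = False,
    remove_outliers: bool = False,
    outlier_policy: str = "single-pass",
) -> MRAnalysis:
    """Run the full pipeline on a validated dataset.

    With fewer than 3 SNPs the MR-Egger stage (and hence Q') is skipped
    and noted; IVW and Cochran's Q are always reported.
    """
    ratios = estimators.compute_ratio_estimates(data)
    ivw = estimators.ivw_estimate(ratios)
    egger = None
    note = None
    try:
        egger = estimators.egger_regression(
            data, random_effects=random_effects, t_inference=t_inference
        )
    except InsufficientInstrumentsError as exc:
        note = str(exc)
    report = heterogeneity.build_pleiotropy_report(data, ivw, egger, fwer=fwer)
    removal = None
    if remove_outliers:
        removal = heterogeneity.remove_outliers_and_refit(
            data, report, policy=outlier_policy, random_effects=random_effects
        )
    return MRAnalysis(
        data=data,
        ivw=ivw,
        egger=egger,
        report=report,
        egger_note=note,
        removal=removal,
    )
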