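"""The McDonald-Kreitman test family.

Contrasts within-species polymorphism counts (Pn, Ps) with between-species
divergence counts (Dn, Ds).  Three variants are provided:

* standard MKT — alpha = 1 - (Ds Pn)/(Dn Ps), neutrality index, Fisher p;
* FWW — polymorphic sites below a frequency cutoff removed before the
  standard formulas, countering segregating weakly deleterious variants;
* extended MKT — the weakly deleterious nonsynonymous polymorphism count is
  estimated from the rare/common frequency split and subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    CorrectionUndefinedError,
    EmptyPolymorphismError,
    FormatError,
    GnselectError,
)

__all__ = [
    "PolymorphismTable", "DivergenceCounts", "MktResult",
    "standard_mkt", "fww_mkt", "extended_mkt", "read_polymorphism_tsv",
]

_CLASSES = ("synonymous", "nonsynonymous")


@dataclass
class PolymorphismTable:
    """Per-site polymorphism records: class and allele frequency in (0,1).

    ``frequency_kind`` records whether frequencies are derived-allele (when
    polarisation is available) or minor-allele fractions.
    """

    df: pd.DataFrame  # columns: site_id, cls, frequency
    frequency_kind: str = "derived"

    def __post_init__(self):
        required = {"site_id", "cls", "frequency"}
        if not required <= set(self.df.columns):
            raise FormatError(
                f"polymorphism table needs columns {sorted(required)}")
        bad_cls = set(self.df["cls"].unique()) - set(_CLASSES)
        if bad_cls:
            raise FormatError(f"unknown site classes: {sorted(bad_cls)}")
        f = self.df["frequency"].to_numpy(dtype=float)
        if len(f) and (np.any(f <= 0.0) or np.any(f >= 1.0)):
            raise FormatError(
                "polymorphism frequencies must lie strictly in (0, 1); "
                "fixed differences belong in the divergence counts")

    @property
    def pn(self) -> int:
        return int((self.df["cls"] == "nonsynonymous").sum())

    @property
    def ps(self) -> int:
        return int((self.df["cls"] == "synonymous").sum())

    def split(self, cutoff: float):
        """(rare, common) partition at the frequency cutoff (rare: f < cutoff)."""
        rare = self.df["frequency"] < cutoff
        return (PolymorphismTable(self.df[rare], self.frequency_kind),
                PolymorphismTable(self.df[~rare], self.frequency_kind))


@dataclass(frozen=True)
class DivergenceCounts:
    dn: int
    ds: int
    ln_sites: float | None = None
    ls_sites: float | None = None

    def __post_init__(self):
        if self.dn < 0 or self.ds < 0:
            raise GnselectError("divergence counts must be nonnegative")


@dataclass
class MktResult:
    variant: str                # standard | FWW | eMKT
    pn_used: float
    ps_used: float
    dn: int
    ds: int
    alpha: float
    neutrality_index: float
    fisher_p: float
    p_wd: float | None = None   # eMKT only
    cutoff: float | None = None
    frequency_kind: str = "derived"
    flags: list = field(default_factory=list)


def _fisher(pn, ps, dn, ds) -> float:
    table = np.array([[pn, ps], [dn, ds]])
    return float(stats.fisher_exact(np.round(table).astype(int),
                                    alternative="two-sided")[1])


def _alpha_ni(pn, ps, dn, ds):
    flags = []
    if ps == 0 or dn == 0:
        flags.append("alpha_undefined")
        return float("nan"), float("nan"), flags
    ni = (pn / ps) / (dn / ds) if ds > 0 else float("nan")
    alpha = 1.0 - (ds * pn) / (dn * ps)
    if not np.isfinite(ni):
        flags.append("ni_undefined")
    return alpha, ni, flags


def standard_mkt(poly: PolymorphismTable, div: DivergenceCounts) -> MktResult:
    """Standard MKT on the raw 2x2 polymorphism/divergence table."""
    pn, ps = poly.pn, poly.ps
    if pn + ps == 0:
        raise EmptyPolymorphismError("no polymorphic sites")
    if div.dn + div.ds == 0:
        raise GnselectError("no divergence counts")
    alpha, ni, flags = _alpha_ni(pn, ps, div.dn, div.ds)
    return MktResult(
        variant="standard", pn_used=pn, ps_used=ps, dn=div.dn, ds=div.ds,
        alpha=alpha, neutrality_index=ni,
        fisher_p=_fisher(pn, ps, div.dn, div.ds),
        frequency_kind=poly.frequency_kind, flags=flags)


def fww_mkt(poly: PolymorphismTable, div: DivergenceCounts,
            cutoff: float = 0.05) -> MktResult:
    """FWW correction: drop polymorphisms with frequency < cutoff, then
    apply the standard formulas to the reduced counts."""
    if not 0.0 <= cutoff < 1.0:
        raise GnselectError(f"cutoff {cutoff} outside [0, 1)")
    _, common = poly.split(cutoff)
    pn, ps = common.pn, common.ps
    if pn + ps == 0:
        raise EmptyPolymorphismError(
            f"no polymorphisms remain above frequency cutoff {cutoff}")
    alpha, ni, flags = _alpha_ni(pn, ps, div.dn, div.ds)
    res = standard_mkt(common, div)
    return MktResult(
        variant="FWW", pn_used=pn, ps_used=ps, dn=div.dn, ds=div.ds,
        alpha=alpha, neutrality_index=ni, fisher_p=res.fisher_p,
        cutoff=cutoff, frequency_kind=poly.frequency_kind, flags=flags)


def extended_mkt(poly: PolymorphismTable, div: DivergenceCounts,
                 cutoff: float = 0.05) -> MktResult:
    """Extended MKT: estimate and remove weakly deleterious rare load.

    P_wd = max(0, Pn_rare - Ps_rare * Pn_common / Ps_common);
    alpha = 1 - (Ds * (Pn - P_wd)) / (Dn * Ps).
    """
    if not 0.0 < cutoff < 1.0:
        raise GnselectError(f"cutoff {cutoff} outside (0, 1)")
    rare, common = poly.split(cutoff)
    if common.ps == 0:
        raise CorrectionUndefinedError(
            "no common synonymous polymorphisms; correction undefined")
    p_wd = max(0.0, rare.pn - rare.ps * (common.pn / common.ps))
    pn_neutral = poly.pn - p_wd
    ps = poly.ps
    alpha, ni, flags = _alpha_ni(pn_neutral, ps, div.dn, div.ds)
    return MktResult(
        variant="eMKT", pn_used=pn_neutral, ps_used=ps, dn=div.dn, ds=div.ds,
        alpha=alpha, neutrality_index=ni,
        fisher_p=_fisher(pn_neutral, ps, div.dn, div.ds),
        p_wd=p_wd, cutoff=cutoff, frequency_kind=poly.frequency_kind,
        flags=flags)


def read_polymorphism_tsv(path, frequency_kind: str = "derived"
                          ) -> PolymorphismTable:
    """Read a `site_id  class  frequency` TSV (class: synonymous|nonsynonymous)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    rename = {"class": "cls"}
    df = df.rename(columns=rename)
    return PolymorphismTable(df[["site_id", "cls", "frequency"]],
                             frequency_kind=frequency_kind)
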