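"""Bench-assay arithmetic: m6A-IP-qPCR, LC-MS/MS curves, bisulfite 5mC.

Three small, exactly testable computations back the sequencing analysis:

* **m6A-IP-qPCR** relative enrichment by the 2^(-dCT) method, with the
  target gene normalized against the ACTIN reference within each fraction
  (IP and input) and the IP fraction then normalized against the input.
* **LC-MS/MS** nucleoside quantification: ordinary least-squares standard
  curves (peak area vs concentration) for A and m6A, inverted to convert
  sample peak areas to concentrations and an m6A/A percentage.
* **Sanger bisulfite** 5mC: per-cytosine methylation level from the C/T
  ratio across pre-aligned clone sequences, with CpG/CHG/CHH context
  called from the reference, and box-plot summaries over a region.

C_T replicates are aggregated by arithmetic mean before exponentiation
(standard ddCT practice); standard curves are fit with a free intercept;
no bisulfite conversion-efficiency correction is applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


# ---------------------------------------------------------------------------
# m6A-IP-qPCR
# ---------------------------------------------------------------------------


@dataclass
class QpcrMeasurement:
    """Technical-replicate C_T values for one gene in IP and input fractions."""

    gene_id: str
    ct_ip_gene: Sequence[float]
    ct_ip_actin: Sequence[float]
    ct_input_gene: Sequence[float]
    ct_input_actin: Sequence[float]

    def __post_init__(self) -> None:
        groups = {
            "ct_ip_gene": self.ct_ip_gene,
            "ct_ip_actin": self.ct_ip_actin,
            "ct_input_gene": self.ct_input_gene,
            "ct_input_actin": self.ct_input_actin,
        }
        sizes = set()
        for name, values in groups.items():
            if len(values) == 0:
                raise ValueError(f"{self.gene_id}: missing C_T values for {name}")
            if any(ct <= 0 for ct in values):
                raise ValueError(f"{self.gene_id}: C_T values must be positive")
            sizes.add(len(values))
        if len(sizes) != 1:
            raise ValueError(
                f"{self.gene_id}: replicate counts must be equal across fractions"
            )


def qpcr_enrichment(m: QpcrMeasurement) -> float:
    """Relative m6A enrichment of the IP fraction over input.

    With group means CT: rel_IP = 2^-(CT_IP,gene - CT_IP,ACTIN);
    rel_in = 2^-(CT_in,gene - CT_in,ACTIN); enrichment = rel_IP / rel_in.
    The ddCT structure makes the result invariant to any constant added to
    all four means.
    """
    d_ip = float(np.mean(m.ct_ip_gene)) - float(np.mean(m.ct_ip_actin))
    d_in = float(np.mean(m.ct_input_gene)) - float(np.mean(m.ct_input_actin))
    return float(2.0 ** (-d_ip) / 2.0 ** (-d_in))


def qpcr_expression(
    ct_gene: Sequence[float] | float, ct_actin: Sequence[float] | float
) -> float:
    """Relative mRNA level: 2^-(CT_gene - CT_ACTIN), means over replicates."""
    return float(2.0 ** -(np.mean(ct_gene) - np.mean(ct_actin)))


# ---------------------------------------------------------------------------
# LC-MS/MS standard curves
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StandardCurve:
    """OLS fit of peak area against nucleoside concentration."""

    nucleoside: str
    concentrations: tuple
    areas: tuple
    slope: float
    intercept: float
    r_squared: float


def fit_standard_curve(
    concentrations: Sequence[float],
    areas: Sequence[float],
    nucleoside: str = "",
) -> StandardCurve:
    """Fit ``area = slope * concentration + intercept`` by least squares.

    Requires at least 3 points with strictly increasing concentrations and
    a positive fitted slope.
    """
    conc = np.asarray(concentrations, dtype=float)
    area = np.asarray(areas, dtype=float)
    if conc.shape != area.shape or conc.ndim != 1:
        raise ValueError("concentrations and areas must be equal-length vectors")
    if len(conc) < 3:
        raise ValueError("standard curve needs at least 3 points")
    if np.any(np.diff(conc) <= 0):
        raise ValueError("concentrations must be strictly increasing")
    res = stats.linregress(conc, area)
    if res.slope <= 0:
        raise ValueError("standard curve slope must be positive")
    return StandardCurve(
        nucleoside=nucleoside,
        concentrations=tuple(conc),
        areas=tuple(area),
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
    )


def quantify(area: float, curve: StandardCurve) -> float:
    """Invert a standard curve: concentration = (area - intercept) / slope."""
    return (area - curve.intercept) / curve.slope


def m6a_ratio(
    area_a: float,
    area_m6a: float,
    curve_a: StandardCurve,
    curve_m6a: StandardCurve,
) -> float:
    """m6A/A ratio in percent from sample peak areas and standard curves."""
    conc_a = quantify(area_a, curve_a)
    conc_m6a = quantify(area_m6a, curve_m6a)
    if conc_a <= 0:
        raise ValueError("adenosine concentration must be positive")
    return 100.0 * conc_m6a / conc_a


# ---------------------------------------------------------------------------
# Sanger bisulfite 5mC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BisulfiteSite:
    """Per-cytosine methylation call from clone C/T ratios."""

    position: int
    context: str  # CpG / CHG / CHH
    n_c: int
    n_t: int
    n_other: int

    @property
    def level(self) -> float:
        return self.n_c / (self.n_c + self.n_t)


def _context(reference: str, i: int) -> str:
    """CpG/CHG/CHH context of the cytosine at ``i`` (H = A, C, or T).

    Missing downstream bases at the sequence end are treated as non-G.
    """
    nxt = reference[i + 1] if i + 1 < len(reference) else ""
    nxt2 = reference[i + 2] if i + 2 < len(reference) else ""
    if nxt == "G":
        return "CpG"
    if nxt2 == "G":
        return "CHG"
    return "CHH"


def bisulfite_levels(reference: str, clones: Sequence[str]) -> list[BisulfiteSite]:
    """Per-cytosine 5mC levels from pre-aligned, gap-free clone sequences.

    For each reference C, clones retaining C are counted as methylated and
    clones converted to T as unmethylated; any other base is tallied as a
    mismatch and ignored in the level. Sites with zero C+T calls are
    excluded with a warning.
    """
    reference = reference.upper()
    clones = [c.upper() for c in clones]
    if not clones:
        raise ValueError("no clone sequences given")
    for idx, clone in enumerate(clones):
        if len(clone) != len(reference):
            raise ValueError(
                f"clone {idx} length {len(clone)} != reference length "
                f"{len(reference)}"
            )
    sites = []
    for i, base in enumerate(reference):
        if base != "C":
            continue
        column = [clone[i] for clone in clones]
        n_c = column.count("C")
        n_t = column.count("T")
        n_other = len(column) - n_c - n_t
        if n_c + n_t == 0:
            warnings.warn(
                f"site {i}: no C/T calls across clones; level undefined, skipped",
                stacklevel=2,
            )
            continue
        sites.append(
            BisulfiteSite(
                position=i, context=_context(reference, i),
                n_c=n_c, n_t=n_t, n_other=n_other,
            )
        )
    return sites


def dmr_summary(
    sites: Sequence[BisulfiteSite], interval: tuple[int, int] | None = None
) -> dict:
    """Box statistics of per-site 5mC levels over a region.

    ``interval`` restricts to sites with position in ``[start, end)``;
    returns mean, median, first/third quartiles, and n.
    """
    if interval is not None:
        s, e = interval
        sites = [site for site in sites if s <= site.position < e]
    if not sites:
        raise ValueError("no sites in the requested region")
    levels = np.array([site.level for site in sites])
    return {
        "mean": float(levels.mean()),
        "median": float(np.median(levels)),
        "q1": float(np.percentile(levels, 25)),
        "q3": float(np.percentile(levels, 75)),
        "n": int(len(levels)),
    }
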