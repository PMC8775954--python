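"""Scalar assay formulas: cytotoxicity, EV purity, dot-blot ratio, qPCR.

Four small, pure computations that accompany the imaging pipeline:

- PI cytotoxicity percent — dead (PI-positive) over total cell counts;
- extracellular-vesicle purity — particle concentration (NTA) over
  protein concentration (BCA), in particles per μg protein;
- dot-blot signal-density ratio — background-normalized integral signal
  of the vesicle lysate relative to whole-tissue lysate, per marker;
- qPCR fold change — ΔΔCq with housekeeping normalization and
  2^(−ΔΔCq) fold change relative to a control group, with optional
  centering of every Cq by the all-sample median (the centering cancels
  in ΔΔCq when applied uniformly, so it is exposed as a toggle).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class AssayInputError(ValueError):
    pass


@dataclass(frozen=True)
class ViabilityCount:
    image_id: str
    pi_positive: int
    total_cells: int

    def __post_init__(self):
        if self.total_cells <= 0:
            raise AssayInputError("total_cells must be positive")
        if not 0 <= self.pi_positive <= self.total_cells:
            raise AssayInputError("pi_positive must be in [0, total_cells]")


def cytotoxicity_percent(pi_positive: int, total_cells: int) -> float:
    """Percent dead cells: 100 × PI-positive / total."""
    count = ViabilityCount("", int(pi_positive), int(total_cells))
    return 100.0 * count.pi_positive / count.total_cells


def ev_purity(particles_per_ml: float, protein_conc_ug_per_ml: float) -> float:
    """Particles per μg protein: NTA concentration / BCA concentration."""
    if particles_per_ml <= 0:
        raise AssayInputError("particle concentration must be positive")
    if protein_conc_ug_per_ml <= 0:
        raise AssayInputError("protein concentration must be positive")
    return particles_per_ml / protein_conc_ug_per_ml


def signal_density_ratio(bev_density: float, tissue_density: float) -> float:
    """Percent: 100 × vesicle-lysate density / tissue-lysate density."""
    if bev_density < 0:
        raise AssayInputError("densities must be nonnegative")
    if tissue_density <= 0:
        raise AssayInputError("tissue density must be positive")
    return 100.0 * bev_density / tissue_density


def qpcr_fold_change(cq: pd.DataFrame, housekeeping: str = "GAPDH",
                     control_group: str = "healthy",
                     median_center: bool = True,
                     n_boot: int = 10_000,
                     seed: int = 0) -> pd.DataFrame:
    """Per-gene, per-group fold change by the ΔΔCq method.

    ``cq`` needs columns ``sample``, ``group``, ``gene``, ``cq``.  Per
    sample: optionally center every Cq by the all-sample median Cq, then
    ΔCq = Cq(gene) − Cq(housekeeping); ΔΔCq subtracts the control group's
    median ΔCq per gene; fold change = 2^(−ΔΔCq).  Returns one row per
    (gene, group) with the median fold change and a seeded bootstrap 95%
    confidence interval.  The control group's own median fold change is 1
    by construction.
    """
    required = {"sample", "group", "gene", "cq"}
    missing = required - set(cq.columns)
    if missing:
        raise AssayInputError(f"Cq table missing columns {sorted(missing)}")
    if not np.isfinite(cq["cq"]).all():
        raise AssayInputError("non-finite Cq values present")
    df = cq.copy()
    if median_center:
        df["cq"] = df["cq"] - df["cq"].median()

    hk = df[df["gene"] == housekeeping].set_index("sample")["cq"]
    no_hk = sorted(set(df["sample"]) - set(hk.index))
    if no_hk:
        raise AssayInputError(f"samples missing housekeeping gene: {no_hk}")
    df = df[df["gene"] != housekeeping].copy()
    df["dcq"] = df["cq"] - df["sample"].map(hk)

    rows = []
    rng = np.random.default_rng(seed)
    for gene, sub in df.groupby("gene", sort=True):
        ctrl = sub.loc[sub["group"] == control_group, "dcq"]
        if ctrl.empty:
            raise AssayInputError(f"no {control_group!r} samples for {gene}")
        ddcq = sub["dcq"] - ctrl.median()
        for group, gsub in ddcq.groupby(sub["group"], sort=True):
            vals = gsub.to_numpy()
            # summarize on the ΔΔCq scale, then transform: keeps the
            # control group's own fold change exactly 1
            med = float(2.0 ** (-np.median(vals)))
            if len(vals) > 1 and n_boot > 0:
                boots = np.median(
                    rng.choice(vals, size=(n_boot, len(vals))), axis=1)
                q_lo, q_hi = np.percentile(boots, [2.5, 97.5])
                lo, hi = float(2.0 ** (-q_hi)), float(2.0 ** (-q_lo))
            else:
                lo = hi = med
            rows.append({"gene": gene, "group": group, "n": len(vals),
                         "fold_change_median": med,
                         "ci95_low": lo, "ci95_high": hi})
    return pd.DataFrame(rows)
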