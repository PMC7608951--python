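"""Classify genes as N/C-dependent vs time-dependent from paired
diploid/haploid expression-by-cycle profiles.

Haploid embryos slow their cell cycles one cycle later than diploids, so
genes whose activation is coupled to cell-cycle slowing ("N/C-dependent"
in the original framing) show a one-cycle delay of their expression
profile in haploids, while "time-dependent" genes do not. This module
implements a transparent shift-fit surrogate for that construct: it
compares the fit error of the haploid profile against the diploid profile
shifted by 0 vs by 1 cycle (toward later cycles, truncated overlap,
mean-squared error after median-centering). Only shifts {0, 1} are
considered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

#: relative fit-error difference below which the call is ambiguous
DEFAULT_AMBIGUITY_TOL = 0.05


@dataclass(frozen=True)
class PloidyProfiles:
    """One gene's expression per cycle in diploid and haploid embryos,
    on a shared cycle axis."""

    gene_id: str
    cycles: tuple[int, ...]
    diploid: tuple[float, ...]
    haploid: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.cycles) == len(self.diploid) == len(self.haploid)):
            raise ValueError(f"{self.gene_id}: profiles must share the cycle axis")
        if not (np.isfinite(self.diploid).all() and np.isfinite(self.haploid).all()):
            raise ValueError(f"{self.gene_id}: non-finite profile values")


class NotClassifiableError(ValueError):
    """The gene shows no activation in the diploid profile."""


def _centered(x: np.ndarray) -> np.ndarray:
    return x - np.median(x)


def classify_delay(
    profiles: PloidyProfiles,
    noise_floor: float,
    tol: float = DEFAULT_AMBIGUITY_TOL,
) -> str:
    """Label one gene 'nc_dependent', 'time_dependent' or 'ambiguous'.

    Requires >= 3 shared cycle points and diploid activation
    (max - min > noise_floor); otherwise raises
    :class:`NotClassifiableError`. After median-centering both profiles,
    the haploid profile is fit against the diploid profile shifted by 0
    and by 1 cycle (toward later cycles, truncated overlap). A strictly
    better 1-cycle fit (by more than ``tol`` relative error difference)
    means nc_dependent; a strictly better 0-shift fit means
    time_dependent; anything closer is ambiguous. The call is invariant
    to adding a constant to both profiles and to uniform positive
    rescaling.
    """
    d = np.asarray(profiles.diploid, dtype=float)
    h = np.asarray(profiles.haploid, dtype=float)
    if len(d) < 3:
        raise NotClassifiableError(f"{profiles.gene_id}: fewer than 3 cycle points")
    if not (d.max() - d.min() > noise_floor):
        raise NotClassifiableError(
            f"{profiles.gene_id}: no diploid activation above the noise floor"
        )
    dc, hc = _centered(d), _centered(h)
    mse0 = float(np.mean((hc - dc) ** 2))
    # haploid at cycle i matches diploid at cycle i-1 (one-cycle delay)
    mse1 = float(np.mean((hc[1:] - dc[:-1]) ** 2))
    scale = max(mse0, mse1)
    if scale == 0 or abs(mse0 - mse1) <= tol * scale:
        return "ambiguous"
    return "nc_dependent" if mse1 < mse0 else "time_dependent"


def classify_cohort(
    profile_table: pd.DataFrame,
    noise_floor: float,
    tol: float = DEFAULT_AMBIGUITY_TOL,
):
    """Classify every gene in a wide profile table.

    ``profile_table`` has one row per gene (index gene ids) and columns
    ``diploid_c<cycle>`` / ``haploid_c<cycle>`` over a shared set of
    cycles. Returns ``(labels, counts, unclassifiable)`` where labels is a
    gene -> label Series, counts a dict over labels, and unclassifiable a
    gene -> reason dict for genes failing the preconditions.
    """
    if profile_table.empty:
        raise ValueError("profile table is empty")
    dip_cols = sorted(
        (c for c in profile_table.columns if c.startswith("diploid_c")),
        key=lambda c: int(c.rsplit("c", 1)[-1]),
    )
    hap_cols = [c.replace("diploid", "haploid") for c in dip_cols]
    missing = set(hap_cols) - set(profile_table.columns)
    if not dip_cols or missing:
        raise ValueError("table must pair diploid_c<k>/haploid_c<k> columns")
    cycles = tuple(int(c.rsplit("c", 1)[-1]) for c in dip_cols)

    labels, failures = {}, {}
    for gene, row in profile_table.iterrows():
        prof = PloidyProfiles(
            gene_id=str(gene),
            cycles=cycles,
            diploid=tuple(row[dip_cols]),
            haploid=tuple(row[hap_cols]),
        )
        try:
            labels[gene] = classify_delay(prof, noise_floor, tol)
        except NotClassifiableError as exc:
            failures[gene] = str(exc)
    labels = pd.Series(labels, name="label")
    counts = {
        "nc_dependent": int((labels == "nc_dependent").sum()),
        "time_dependent": int((labels == "time_dependent").sum()),
        "ambiguous": int((labels == "ambiguous").sum()),
        "unclassifiable": len(failures),
    }
    return labels, counts, failures
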