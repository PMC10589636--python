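"""Subclonal signature trajectories via CCF-ordered exposure binning.

Mutations are sorted by descending cancer cell fraction and split into
equal-count bins; signature exposures are refit per bin with all relative-
exposure cutoffs set to zero, and the highest- vs lowest-CCF endpoint pair
per signature supports group-level contrasts of clonal vs subclonal
activity.  This replaces changepoint-based trajectory segmentation with a
fixed binning that preserves the endpoint comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .catalogs import build_catalog
from .signature_inference import ExposureTable, SignatureMatrix, fit_exposures
from .variant_io import SnvRecord

log = logging.getLogger(__name__)


@dataclass
class CcfBin:
    index: int
    ccf_high: float
    ccf_low: float
    snvs: list[SnvRecord]


def bin_by_ccf(snvs, n_bins: int = 10, min_per_bin: int = 50) -> list[CcfBin]:
    """Split mutations with defined CCF into equal-count bins ordered from
    highest to lowest CCF.  With fewer than ``n_bins * min_per_bin``
    mutations the bin count degrades (at least one bin); ties at boundaries
    break by a stable (chrom, pos) sort."""
    with_ccf = [s for s in snvs if s.ccf is not None]
    if not with_ccf:
        raise ValueError("no mutations with a defined CCF")
    with_ccf.sort(key=lambda s: (s.chrom, s.pos))
    with_ccf.sort(key=lambda s: -s.ccf)  # stable: position order retained within ties
    n = len(with_ccf)
    k = min(n_bins, max(1, n // min_per_bin))
    if k < n_bins:
        log.info("bin_by_ccf: %d mutations support only %d bins", n, k)
    edges = [round(i * n / k) for i in range(k + 1)]
    bins = []
    for b in range(k):
        chunk = with_ccf[edges[b]:edges[b + 1]]
        bins.append(CcfBin(index=b, ccf_high=chunk[0].ccf, ccf_low=chunk[-1].ccf,
                           snvs=chunk))
    return bins


def trajectory(bins: list[CcfBin], signatures: SignatureMatrix, reference,
               ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-bin relative exposures plus the per-signature endpoint pair.

    Returns (long-format trajectory frame with columns bin, ccf_high,
    ccf_low, signature, relative_exposure; endpoint frame indexed by
    signature with columns highest_ccf, lowest_ccf).
    """
    rows = []
    nonempty = []
    for b in bins:
        if not b.snvs:
            log.info("trajectory: empty CCF bin %d skipped", b.index)
            continue
        catalog = build_catalog(b.snvs, signatures.scheme, reference,
                                samples=[b.snvs[0].sample_id])
        expo = fit_exposures(catalog, signatures, per_signature_cutoffs=None)
        rel = expo.relative.iloc[0]
        nonempty.append(b)
        for name in signatures.names:
            rows.append({"bin": b.index, "ccf_high": b.ccf_high, "ccf_low": b.ccf_low,
                         "signature": name, "relative_exposure": float(rel[name])})
    traj = pd.DataFrame(rows)
    if not nonempty:
        return traj, pd.DataFrame(columns=["highest_ccf", "lowest_ccf"])
    first, last = nonempty[0].index, nonempty[-1].index
    wide = traj.pivot(index="signature", columns="bin", values="relative_exposure")
    endpoints = pd.DataFrame({"highest_ccf": wide[first], "lowest_ccf": wide[last]})
    endpoints = endpoints.loc[signatures.names]
    return traj, endpoints


def vaf_to_ccf(vaf: float, purity: float, cn_total: int) -> float:
    """Standard conversion ccf = vaf * (purity * cn_total + 2 (1 - purity)) / purity,
    capped at 1 (diploid normal, single mutated copy)."""
    if purity <= 0:
        raise ValueError("purity must be positive")
    return min(1.0, vaf * (purity * cn_total + 2.0 * (1.0 - purity)) / purity)
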