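"""BaP-equivalent toxicity (TEQ) and its apportionment to PMF sources.

The carcinogenic potency of a PAH mixture is summarized as a BaP-equivalent
concentration,

    BaP_TEQ = sum_i TEF_i * C_i   (ng/g),

weighting each compound by its toxic equivalency factor. Given a normalized
factorization (S, f), the mass of compound i attributed to source p in sample
k is (PAH_i)_kp = S_kp * f_ip, so each source's toxicity contribution is

    (BaP_TEQ)_kp = sum_i TEF_i * S_kp * f_ip,

and the per-source TEQ shares follow by summing over samples. Shares are
computed on the model reconstruction S f (not raw data), so they sum to 100%
exactly: the residual carries no apportionable toxicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import CompoundCatalog, default_catalog
from .pmf import NormalizedModel

__all__ = ["ToxicityApportionment", "bap_teq", "apportion_teq", "teq_source_share_report"]


@dataclass
class ToxicityApportionment:
    """Per-sample, per-source toxicity attribution from a normalized model."""

    species_contributions: np.ndarray  # (n, p, 16): (PAH_i)_kp, ng/g
    teq: np.ndarray  # (n, p): (BaP_TEQ)_kp, ng/g BaP-equivalents
    shares: np.ndarray  # (p,): percent of total TEQ per source
    source_names: list[str] | None = None

    def sample_teq(self) -> np.ndarray:
        """Total TEQ of each sample's model reconstruction."""
        return self.teq.sum(axis=1)


def bap_teq(sample, catalog: CompoundCatalog | None = None) -> float:
    """BaP-equivalent concentration of one length-16 concentration vector."""
    catalog = catalog or default_catalog()
    sample = np.asarray(sample, dtype=float)
    if sample.shape != (len(catalog),):
        raise ValueError(f"expected a length-{len(catalog)} concentration vector, got shape {sample.shape}")
    if np.any(sample < 0):
        raise ValueError("concentrations must be non-negative")
    return float(sample @ np.asarray(catalog.tefs))


def apportion_teq(normalized: NormalizedModel, catalog: CompoundCatalog | None = None) -> ToxicityApportionment:
    """Apportion BaP-equivalent toxicity to the sources of a normalized model."""
    catalog = catalog or normalized.catalog
    tefs = np.asarray(catalog.tefs)
    # (PAH_i)_kp = S_kp * f_ip  -> (n, p, m)
    species = normalized.S[:, :, None] * normalized.f[None, :, :]
    teq = species @ tefs  # (n, p)
    total = teq.sum()
    shares = 100.0 * teq.sum(axis=0) / total if total > 0 else np.zeros(normalized.n_sources)
    names = [lab.name for lab in normalized.labels] if normalized.labels else None
    return ToxicityApportionment(species_contributions=species, teq=teq, shares=shares, source_names=names)


def teq_source_share_report(apportionments: dict[str, ToxicityApportionment]) -> pd.DataFrame:
    """Long-format share table (group x source x percent), one group per key."""
    rows = []
    for group, app in apportionments.items():
        names = app.source_names or [f"factor{k + 1}" for k in range(len(app.shares))]
        for name, share in zip(names, app.shares):
            rows.append({"group": group, "source": name, "teq_share_percent": share})
    return pd.DataFrame(rows, columns=["group", "source", "teq_share_percent"])
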