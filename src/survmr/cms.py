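"""Consensus-molecular-subtype enrichment of causal genes.

Each causal gene's expression is dichotomized at the median computed across
all samples; the side of the split associated with longer survival (given the
gene's causal direction on the hazard) is "beneficial", the other side
"non-beneficial".  A subtype is enriched for a gene when strictly more than
70% of its patients fall in one category.

Conventions
-----------
* Samples exactly at the median are assigned to the "low" side.
* ``effect_direction`` is the sign of the gene's causal effect on the hazard:
  -1 (higher expression lowers the hazard, i.e. protective) makes "high" the
  beneficial side; +1 makes "low" beneficial.
* Enrichment depends only on median ranks, hence is invariant to any
  monotone transform of expression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from survmr.containers import ExpressionMatrix

ENRICHMENT_RATE = 0.70
SUBTYPES = ("CMS1", "CMS2", "CMS3", "CMS4")


@dataclass
class EnrichmentResult:
    gene_id: str
    subtype: str
    category: str  # beneficial | non_beneficial
    rate: float
    enriched: bool
    n_subtype: int


def dichotomize(E: ExpressionMatrix, gene_id: str, effect_direction: int) -> pd.Series:
    """Per-sample beneficial / non-beneficial category for one gene."""
    if effect_direction not in (-1, 1):
        raise ValueError("effect_direction must be -1 or +1 (sign of the hazard effect)")
    x = E.values.loc[gene_id].astype(float)
    if x.nunique() == 1:
        raise ValueError(f"gene {gene_id!r} has zero expression variance")
    med = float(np.median(x))
    high = x > med  # ties at the median go to the low side
    beneficial_is_high = effect_direction == -1
    beneficial = high if beneficial_is_high else ~high
    return pd.Series(
        np.where(beneficial, "beneficial", "non_beneficial"), index=x.index, name=gene_id
    )


def enrichment(categories: pd.Series, subtype_labels: pd.Series, threshold: float = ENRICHMENT_RATE):
    """Per-subtype beneficial / non-beneficial rates and enrichment calls.

    Rates within a subtype sum to 1; ``enriched`` requires a rate strictly
    above ``threshold``.  Subtypes without samples are omitted with a warning.
    """
    missing = categories.index.difference(subtype_labels.index)
    if len(missing):
        raise ValueError(f"samples lack a subtype label: {list(missing[:5])}")
    labels = subtype_labels.loc[categories.index]
    out = []
    for st in SUBTYPES:
        members = categories[labels == st]
        if len(members) == 0:
            warnings.warn(f"subtype {st} has no samples; omitted", stacklevel=2)
            continue
        for cat in ("beneficial", "non_beneficial"):
            rate = float((members == cat).mean())
            out.append(
                EnrichmentResult(
                    gene_id=str(categories.name),
                    subtype=st,
                    category=cat,
                    rate=rate,
                    enriched=bool(rate > threshold),
                    n_subtype=len(members),
                )
            )
    return out


def enrich_causal_genes(
    E: ExpressionMatrix,
    mr_results,
    subtype_labels: pd.Series,
    threshold: float = ENRICHMENT_RATE,
) -> pd.DataFrame:
    """Run the enrichment analysis for every causal MR hit.

    ``mr_results`` is an iterable of objects with ``gene_id`` and
    ``direction`` attributes (one-sample MR hits).  Returns a tidy frame with
    one row per (gene, subtype, category).
    """
    rows = []
    seen = set()
    for r in mr_results:
        if r.gene_id in seen or r.direction == 0:
            continue
        seen.add(r.gene_id)
        cats = dichotomize(E, r.gene_id, int(r.direction))
        for res in enrichment(cats, subtype_labels, threshold):
            rows.append(vars(res))
    return pd.DataFrame(rows)
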