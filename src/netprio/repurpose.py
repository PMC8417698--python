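"""Drug-target joining: per-gene max development phase and category enrichment.

Phase IV targets are "approved"; phases I-III are "phased"; phase 0 rows
(preclinical only) and genes absent from the drug table map to "none".
"""

from __future__ import annotations

import warnings
from typing import Iterable

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .enrichment import fisher_enrichment
from .genesets import GeneSetCollection

__all__ = ["max_phase_targets", "category_enrichment"]

REQUIRED_COLUMNS = ("gene", "drug", "phase", "indication", "moa")


def _validate(drugs: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in drugs.columns]
    if missing:
        raise ValueError(f"drug table missing columns: {missing}")
    phases = drugs["phase"].astype(int)
    if not phases.isin([0, 1, 2, 3, 4]).all():
        bad = sorted(phases[~phases.isin([0, 1, 2, 3, 4])].unique())
        raise ValueError(f"phases outside 0-4: {bad}")
    dup = drugs.duplicated(subset=["gene", "drug", "indication"])
    out = drugs.loc[~dup].copy()
    out["phase"] = out["phase"].astype(int)
    return out


def _category(max_phase: int) -> str:
    if max_phase == 4:
        return "approved"
    if 1 <= max_phase <= 3:
        return "phased"
    return "none"


def max_phase_targets(
    drugs: pd.DataFrame,
    genes: Iterable[str] | None = None,
    indication: str | None = None,
) -> pd.DataFrame:
    """Per-gene maximum development phase and target category.

    All drugs attaining the max phase are listed (comma-joined, sorted).
    ``genes`` optionally extends the output with genes absent from the table
    (category "none"). ``indication`` restricts the table before aggregation.
    """
    table = _validate(drugs)
    if indication is not None:
        table = table[table["indication"] == indication]
    rows = []
    for gene, grp in table.groupby("gene", sort=True):
        mp = int(grp["phase"].max())
        support = sorted(grp.loc[grp["phase"] == mp, "drug"].unique())
        rows.append(
            {
                "gene": gene,
                "category": _category(mp),
                "max_phase": mp,
                "drugs": ",".join(support),
            }
        )
    seen = {r["gene"] for r in rows}
    if genes is not None:
        for g in sorted(set(genes) - seen):
            rows.append({"gene": g, "category": "none", "max_phase": 0, "drugs": ""})
    return pd.DataFrame(rows).sort_values("gene", ignore_index=True)


def category_enrichment(
    crosstalk_genes: Iterable[str],
    categories: pd.DataFrame,
    universe: Iterable[str],
) -> pd.DataFrame:
    """One-sided Fisher enrichment of crosstalk genes in approved/phased targets.

    Empty categories yield p = 1 with a warning. BH correction spans the two
    tests.
    """
    universe = frozenset(universe)
    query = frozenset(crosstalk_genes) & universe
    frames = []
    for cat in ("approved", "phased"):
        members = set(categories.loc[categories["category"] == cat, "gene"]) & universe
        if not members:
            warnings.warn(
                f"category {cat!r} has no targets in the universe", stacklevel=2
            )
            frames.append(
                pd.DataFrame(
                    [
                        {
                            "set_id": cat,
                            "k": 0,
                            "n": len(query),
                            "K": 0,
                            "N": len(universe),
                            "Z": float("nan"),
                            "OR": float("nan"),
                            "CI_low": float("nan"),
                            "CI_high": float("nan"),
                            "p": 1.0,
                        }
                    ]
                )
            )
            continue
        sets = GeneSetCollection([(cat, f"{cat} drug targets", members)])
        frames.append(fisher_enrichment(query, sets, universe))
    enr = pd.concat(frames, ignore_index=True)
    enr["FDR"] = multipletests(enr["p"], method="fdr_bh")[1]
    return enr.rename(columns={"set_id": "category"})
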