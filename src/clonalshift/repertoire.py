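"""TCR repertoire statistics from paired clonotype tables.

Clonotypes are identified by (v_call, j_call, junction) — the nucleotide
CDR3 junction together with its V and J gene calls.  Repertoire evenness is
summarized by Simpson-family indices of the clone-proportion concentration
``lambda = sum(p_i^2)``; the default Gini-Simpson form ``1 - lambda`` is
high for an even repertoire and low under clonal expansion, so a negative
log2 fold change of the index between paired pre- and post-treatment
samples indicates expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns identifying a clonotype
IDENTITY_KEY = ["v_call", "j_call", "junction"]

REQUIRED_COLUMNS = ["v_call", "j_call", "junction", "duplicate_count"]

VARIANTS = ("gini_simpson", "inverse_simpson", "simpson_concentration")

DEFAULT_EPSILON = 1e-6


@dataclass
class ClonotypeTable:
    """Clonotypes with abundance counts for one patient/timepoint/chain.

    ``clones`` holds one row per distinct (v_call, j_call, junction) with a
    nonnegative integer ``count`` column.
    """

    patient_id: str
    timepoint: str
    chain: str
    clones: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in IDENTITY_KEY + ["count"] if c not in self.clones.columns]
        if missing:
            raise ValueError(f"clonotype frame missing columns {missing}")
        if self.clones.duplicated(IDENTITY_KEY).any():
            raise ValueError("duplicate clonotype identity keys in table")
        if (self.clones["count"] < 0).any():
            raise ValueError("negative clonotype counts")

    @property
    def total_count(self) -> int:
        return int(self.clones["count"].sum())

    def __len__(self) -> int:
        return len(self.clones)


@dataclass
class DiversityRecord:
    """Paired Simpson diversity values and their log2 fold change."""

    patient_id: str
    chain: str
    di_pre: float
    di_post: float
    di_logfc: float
    variant: str
    epsilon: float = DEFAULT_EPSILON

    @property
    def expansion(self) -> bool:
        """Negative DI logFC marks post-treatment clonal expansion."""
        return self.di_logfc < 0


@dataclass
class ExpansionProfile:
    """Mass of the top post-treatment clones, paired with their pre mass."""

    patient_id: str
    chain: str
    n_top: int
    top_clone_keys: List[Tuple[str, str, str]]
    mass_post: float
    mass_pre: float
    per_clone: pd.DataFrame = field(repr=False)


def read_clonotypes(path, patient_id: str, timepoint: str, chain: str) -> ClonotypeTable:
    """Read an AIRR Rearrangement TSV into a :class:`ClonotypeTable`.

    Rows sharing an identity key are merged by summing ``duplicate_count``;
    rows with a missing junction or count are dropped with a logged tally.
    """
    df = pd.read_csv(path, sep="\t", dtype={"junction": "string", "v_call": "string",
                                            "j_call": "string"})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"AIRR file {path} lacks required column(s): {', '.join(missing)}")
    n_raw = len(df)
    bad = (
        df["junction"].isna()
        | (df["junction"].astype("string").str.len() == 0)
        | df["duplicate_count"].isna()
    )
    if bad.any():
        logger.warning("%s: dropped %d/%d rows with missing junction or count",
                       path, int(bad.sum()), n_raw)
    df = df.loc[~bad]
    if df.empty:
        raise ValueError(f"{path}: no usable clonotype rows after filtering")
    merged = (
        df.assign(count=df["duplicate_count"].astype(int))
        .groupby(IDENTITY_KEY, as_index=False, sort=True)["count"]
        .sum()
    )
    table = ClonotypeTable(patient_id, timepoint, chain, merged)
    if table.total_count <= 0:
        raise ValueError(f"{path}: total clonotype count is zero")
    return table


def write_clonotypes(table: ClonotypeTable, path) -> None:
    """Write a table as AIRR Rearrangement TSV (v_call, j_call, junction, duplicate_count)."""
    out = table.clones[IDENTITY_KEY].copy()
    out.insert(0, "sequence_id", [f"{table.patient_id}_{table.timepoint}_{i}"
                                  for i in range(len(out))])
    out["duplicate_count"] = table.clones["count"].to_numpy()
    out.to_csv(path, sep="\t", index=False)


def clone_proportions(table: ClonotypeTable) -> np.ndarray:
    """Clone proportions p_i = count_i / total; sums to 1."""
    counts = table.clones["count"].to_numpy(dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("total clonotype count is zero")
    return counts / total


def simpson_di(p: np.ndarray, variant: str = "gini_simpson") -> float:
    """Simpson diversity of a proportion vector.

    ``lambda = sum(p^2)`` is the concentration; ``gini_simpson`` returns
    ``1 - lambda`` (default), ``inverse_simpson`` returns ``1/lambda`` and
    ``simpson_concentration`` returns ``lambda`` itself.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValueError("empty proportion vector")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError(f"proportions sum to {p.sum()}, expected 1")
    lam = float(np.sum(p * p))
    if variant == "gini_simpson":
        return 1.0 - lam
    if variant == "inverse_simpson":
        return 1.0 / lam
    if variant == "simpson_concentration":
        return lam
    raise ValueError(f"unknown variant {variant!r}; choose from {VARIANTS}")


def di_logfc(
    pre: ClonotypeTable,
    post: ClonotypeTable,
    variant: str = "gini_simpson",
    epsilon: float = DEFAULT_EPSILON,
) -> DiversityRecord:
    """log2((DI_post + eps) / (DI_pre + eps)) for a matched pre/post pair.

    The small ``epsilon`` guards monoclonal repertoires whose Gini-Simpson
    index is exactly zero.
    """
    if pre.patient_id != post.patient_id or pre.chain != post.chain:
        raise ValueError(
            f"pre ({pre.patient_id}/{pre.chain}) and post "
            f"({post.patient_id}/{post.chain}) tables do not match"
        )
    if len(pre) == 0 or len(post) == 0:
        raise ValueError("empty clonotype table")
    d_pre = simpson_di(clone_proportions(pre), variant)
    d_post = simpson_di(clone_proportions(post), variant)
    lfc = float(np.log2((d_post + epsilon) / (d_pre + epsilon)))
    return DiversityRecord(pre.patient_id, pre.chain, d_pre, d_post, lfc, variant, epsilon)


def top_clone_mass(
    pre: ClonotypeTable, post: ClonotypeTable, n_top: Optional[int] = 200
) -> ExpansionProfile:
    """Mass of the top-``n_top`` post clones, and the same clones' pre mass.

    Post clones are ranked by count (descending), ties broken by the
    lexicographic order of the identity key.  ``mass_pre`` sums the pre
    proportions of exactly those identity keys (0 when absent pre).
    ``n_top=None`` means all post clones.
    """
    if pre.patient_id != post.patient_id or pre.chain != post.chain:
        raise ValueError("pre and post tables do not match on patient/chain")
    if n_top is not None and n_top < 1:
        raise ValueError("n_top must be >= 1")
    post_df = post.clones.sort_values(
        ["count"] + IDENTITY_KEY, ascending=[False, True, True, True], kind="mergesort"
    ).reset_index(drop=True)
    k = len(post_df) if n_top is None else min(n_top, len(post_df))
    top = post_df.iloc[:k].copy()
    p_post_all = post.total_count
    p_pre_all = pre.total_count
    pre_lookup = pre.clones.set_index(IDENTITY_KEY)["count"]
    keys = list(top[IDENTITY_KEY].itertuples(index=False, name=None))
    pre_counts = np.array(
        [pre_lookup.get(key, 0) for key in keys], dtype=float
    )
    top["p_post"] = top["count"].to_numpy(dtype=float) / p_post_all
    top["p_pre"] = pre_counts / p_pre_all
    top = top.drop(columns=["count"])
    return ExpansionProfile(
        patient_id=post.patient_id,
        chain=post.chain,
        n_top=k,
        top_clone_keys=keys,
        mass_post=float(top["p_post"].sum()),
        mass_pre=float(top["p_pre"].sum()),
        per_clone=top,
    )
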