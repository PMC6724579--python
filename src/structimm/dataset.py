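"""Peptide pool ingestion, curation and positional hydropathy comparison.

Three pools are modeled: ``immunogenic`` (epitopes with strong T cell assay
evidence), ``self`` (MHC-presented self-ligandome peptides, presumed
non-immunogenic) and ``nonbinder`` (peptides incompatible with the target
allele).  Curation keeps HLA-A2 nonamers, applies the response-frequency
evidence threshold to the immunogenic pool, collapses duplicates and
assigns the binary target: immunogenic -> 1, self and nonbinder -> 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EncodingError, ParseError
from .features import wimley_white_scale
from .structmodel import AA_ALPHABET

log = logging.getLogger(__name__)

POOLS = ("immunogenic", "self", "nonbinder")

# accepted spellings of the target allele
_A2_ALIASES = {"HLA-A2", "HLA-A*02:01", "HLA-A*0201", "HLA-A*02", "A2",
               "A*02:01", "A*0201", "A0201"}


def is_hla_a2(allele: str) -> bool:
    return allele.strip().upper().replace(" ", "") in _A2_ALIASES


@dataclass
class PeptideRecord:
    sequence: str
    pool: str
    allele: str = "HLA-A*02:01"
    response_frequency: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pool not in POOLS:
            raise ValueError(f"pool must be one of {POOLS}, got {self.pool!r}")
        self.sequence = self.sequence.upper()


@dataclass
class CurationRules:
    length: int = 9
    require_allele: bool = True
    min_response_frequency: float = 50.0


@dataclass
class LabeledDataset:
    records: list[PeptideRecord]
    y: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]

    @property
    def pools(self) -> np.ndarray:
        return np.array([r.pool for r in self.records])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sequence": self.sequences,
            "pool": [r.pool for r in self.records],
            "allele": [r.allele for r in self.records],
            "response_frequency": [r.response_frequency for r in self.records],
            "provenance": [r.provenance for r in self.records],
            "y": self.y.astype(int),
        })


def read_records(path) -> list[PeptideRecord]:
    """Read peptide records from delimited text (TSV or CSV)."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    try:
        df = pd.read_csv(path, sep=sep, comment="#")
    except Exception as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if "sequence" not in df.columns or "pool" not in df.columns:
        raise ParseError(f"{path}: need at least 'sequence' and 'pool' columns")
    records = []
    for _, row in df.iterrows():
        rf = row.get("response_frequency")
        records.append(PeptideRecord(
            sequence=str(row["sequence"]),
            pool=str(row["pool"]),
            allele=str(row.get("allele", "HLA-A*02:01")),
            response_frequency=None if pd.isna(rf) else float(rf),
            provenance=str(row.get("provenance", "")),
        ))
    return records


def curate(records: list[PeptideRecord],
           rules: CurationRules | None = None) -> LabeledDataset:
    """Filter, deduplicate and label records.

    Kept: correct length, valid alphabet, allele matching the target
    (nonbinders are exempt from the allele requirement — they are defined by
    incompatibility) and, for the immunogenic pool, response frequency at or
    above the evidence threshold.  Duplicate (sequence, pool) entries are
    collapsed; a sequence present both as immunogenic and non-immunogenic
    keeps the immunogenic assignment (logged).
    """
    rules = rules or CurationRules()
    kept: dict[tuple[str, str], PeptideRecord] = {}
    for rec in records:
        seq = rec.sequence
        if len(seq) != rules.length:
            log.debug("reject %s: length %d", seq, len(seq))
            continue
        if set(seq) - set(AA_ALPHABET):
            log.warning("reject %s: invalid alphabet", seq)
            continue
        if (rules.require_allele and rec.pool != "nonbinder"
                and not is_hla_a2(rec.allele)):
            log.debug("reject %s: allele %s", seq, rec.allele)
            continue
        if rec.pool == "immunogenic":
            rf = rec.response_frequency
            if rf is None or rf < rules.min_response_frequency:
                log.debug("reject %s: response frequency %s", seq, rf)
                continue
        kept.setdefault((seq, rec.pool), rec)
    # cross-pool conflicts: immunogenic assignment wins
    by_seq: dict[str, PeptideRecord] = {}
    for (seq, _pool), rec in kept.items():
        prev = by_seq.get(seq)
        if prev is None:
            by_seq[seq] = rec
        elif prev.pool != rec.pool:
            winner = rec if rec.pool == "immunogenic" else prev
            log.warning("sequence %s appears in pools %s and %s; keeping %s",
                        seq, prev.pool, rec.pool, winner.pool)
            by_seq[seq] = winner
    out = list(by_seq.values())
    y = np.array([1 if r.pool == "immunogenic" else 0 for r in out], dtype=int)
    return LabeledDataset(records=out, y=y)


def positional_hydropathy_compare(pool_a: list[str], pool_b: list[str],
                                  test: str = "welch",
                                  n_permutations: int = 10000,
                                  seed: int = 0) -> pd.DataFrame:
    """Per-position mean hydropathy difference (A - B) with significance.

    Negative differences mean pool A is more hydrophobic at that position
    (the Wimley-White interface scale is negative for hydrophobic residues).
    Welch's two-sample t-test by default; a permutation test is available.
    Raw p-values are reported with a Bonferroni column across the nine
    positions.
    """
    if not pool_a or not pool_b:
        raise ValueError("both pools must be non-empty")
    for seq in list(pool_a) + list(pool_b):
        if len(seq) != 9:
            raise EncodingError(f"all peptides must be nonamers, got {seq!r}")
    scale = wimley_white_scale()
    a = np.array([[scale[aa] for aa in s] for s in pool_a])
    b = np.array([[scale[aa] for aa in s] for s in pool_b])
    rows = []
    rng = np.random.default_rng(seed)
    for pos in range(9):
        xa, xb = a[:, pos], b[:, pos]
        diff = float(xa.mean() - xb.mean())
        if test == "welch":
            if np.var(xa) == 0 and np.var(xb) == 0:
                p = 1.0 if diff == 0 else 0.0
            else:
                p = float(stats.ttest_ind(xa, xb, equal_var=False).pvalue)
        elif test == "permutation":
            pooled = np.concatenate([xa, xb])
            obs = abs(diff)
            count = 0
            for _ in range(n_permutations):
                perm = rng.permutation(pooled)
                d = perm[:len(xa)].mean() - perm[len(xa):].mean()
                if abs(d) >= obs - 1e-12:
                    count += 1
            p = (count + 1) / (n_permutations + 1)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append({"position": pos + 1, "mean_diff": diff, "p": p})
    df = pd.DataFrame(rows)
    df["p_bonferroni"] = np.minimum(df["p"] * 9, 1.0)
    return df
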