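"""Core in-memory containers for counts, metadata, scores and drug tables.

Matrices are held as pandas DataFrames (genes as the index, samples as
columns); the classes here add validation and the small amount of typed
structure the analysis layers rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MEASURES = ("SD", "CV", "MAD", "DM", "EV", "LCV")

SEX_ALIASES = {
    "m": "male",
    "male": "male",
    "f": "female",
    "female": "female",
}


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


def _check_unique(values, kind: str) -> None:
    idx = pd.Index(values)
    if idx.has_duplicates:
        dup = idx[idx.duplicated()][0]
        raise ValidationError(f"duplicate {kind} id: {dup!r}")


@dataclass
class CountMatrix:
    """Raw integer read counts, genes x samples."""

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        _check_unique(df.index, "gene")
        _check_unique(df.columns, "sample")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.all(np.isfinite(values.astype(float))):
                raise ValidationError("counts contain missing or non-finite cells")
            if not np.all(values == np.floor(values)):
                raise ValidationError("counts must be integers")
            df = df.astype(np.int64)
        if values.size and (df.to_numpy() < 0).any():
            raise ValidationError("negative count")
        self.counts = df

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_samples(self, sample_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[:, list(sample_ids)])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        return CountMatrix(self.counts.loc[list(gene_ids)])

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def __eq__(self, other) -> bool:
        return isinstance(other, CountMatrix) and self.counts.equals(other.counts)


@dataclass
class SampleMeta:
    """Per-sample annotations: tissue, sex and cause of death.

    ``sex`` is normalized to {male, female} where recognized; any other
    label is retained verbatim and simply excluded from sex-stratified
    analyses.
    """

    table: pd.DataFrame  # index: sample_id; columns: tissue, sex, death_cause

    REQUIRED = ("tissue", "sex", "death_cause")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"sample metadata missing column(s): {missing}")
        sex = self.table["sex"].astype(str).str.strip()
        self.table = self.table.assign(
            sex=[SEX_ALIASES.get(s.lower(), s) for s in sex]
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def samples_of(self, tissue: str) -> list[str]:
        return list(self.table.index[self.table["tissue"] == tissue])

    def check_covers(self, counts: CountMatrix) -> None:
        missing = set(counts.sample_ids) - set(self.table.index)
        if missing:
            raise ValidationError(
                f"samples without metadata: {sorted(missing)[:5]}"
            )

    def __eq__(self, other) -> bool:
        return isinstance(other, SampleMeta) and self.table.equals(other.table)


@dataclass
class GeneAnnotation:
    """Chromosome and biotype per gene (one row per gene id)."""

    table: pd.DataFrame  # index: gene_id; columns: chromosome, is_protein_coding

    REQUIRED = ("chromosome", "is_protein_coding")

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "gene")
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"gene annotation missing column(s): {missing}")
        self.table = self.table.assign(
            is_protein_coding=self.table["is_protein_coding"].astype(bool)
        )

    def sex_chromosome_genes(self) -> set[str]:
        chrom = self.table["chromosome"].astype(str).str.removeprefix("chr")
        return set(self.table.index[chrom.isin(["X", "Y"])])

    def __eq__(self, other) -> bool:
        return isinstance(other, GeneAnnotation) and self.table.equals(other.table)


@dataclass
class VariabilityParams:
    """Knobs of the variability pipeline.

    window_m
        Sliding-window size (genes) for the local measures; 500 by default.
    ev_nn
        Nearest-neighbor span of the local regression behind EV.
    cpm_threshold, expressed_fraction
        A gene enters a tissue's frame only if its cpm is strictly above
        ``cpm_threshold`` in at least ``ceil(expressed_fraction * n)`` of the
        tissue's samples.
    cv_ddof
        Delta-degrees-of-freedom of the standard deviation behind CV/SD.
    """

    window_m: int = 500
    ev_nn: float = 0.3
    cpm_threshold: float = 0.0
    expressed_fraction: float = 0.8
    cv_ddof: int = 1

    def __post_init__(self) -> None:
        if self.window_m < 2:
            raise ValidationError("window_m must be >= 2")
        if not (0.0 < self.expressed_fraction <= 1.0):
            raise ValidationError("expressed_fraction must be in (0, 1]")
        if not (0.0 < self.ev_nn <= 1.0):
            raise ValidationError("ev_nn must be in (0, 1]")
        if self.cpm_threshold < 0:
            raise ValidationError("cpm_threshold must be >= 0")
        if self.cv_ddof not in (0, 1):
            raise ValidationError("cv_ddof must be 0 or 1")


class VariabilityTable:
    """Long-format (gene, tissue, measure) -> score table.

    Also carries the gene's median cpm in that tissue, so expression-bias
    diagnostics can be computed from the table alone.
    """

    COLUMNS = ("gene_id", "tissue", "measure", "score", "median_expression")

    def __init__(self, table: pd.DataFrame | None = None):
        if table is None:
            table = pd.DataFrame(columns=list(self.COLUMNS))
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"variability table missing column(s): {missing}")
        bad = set(table["measure"]) - set(MEASURES)
        if bad:
            raise ValidationError(f"unknown measure(s): {sorted(bad)}")
        lcv = table.loc[table["measure"] == "LCV", "score"]
        if len(lcv) and ((lcv < 0).any() or (lcv > 100).any()):
            raise ValidationError("LCV scores must lie in [0, 100]")
        self.table = table[list(self.COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VariabilityTable):
            return False
        a = self.table.sort_values(["gene_id", "tissue", "measure"]).reset_index(drop=True)
        b = other.table.sort_values(["gene_id", "tissue", "measure"]).reset_index(drop=True)
        return a.equals(b)

    def measures(self) -> list[str]:
        return sorted(self.table["measure"].unique())

    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def pivot(self, measure: str) -> pd.DataFrame:
        """Gene x tissue wide matrix of one measure (NaN where unscored)."""
        sub = self.table[self.table["measure"] == measure]
        return sub.pivot(index="gene_id", columns="tissue", values="score")

    def scores(self, measure: str, tissue: str) -> pd.Series:
        sub = self.table[
            (self.table["measure"] == measure) & (self.table["tissue"] == tissue)
        ]
        return pd.Series(sub["score"].to_numpy(), index=sub["gene_id"].to_numpy())

    def median_expression(self, tissue: str) -> pd.Series:
        sub = self.table[self.table["tissue"] == tissue]
        sub = sub.drop_duplicates("gene_id")
        return pd.Series(
            sub["median_expression"].to_numpy(), index=sub["gene_id"].to_numpy()
        )

    @staticmethod
    def concat(tables: list["VariabilityTable"]) -> "VariabilityTable":
        frames = [t.table for t in tables if len(t)]
        if not frames:
            return VariabilityTable()
        return VariabilityTable(pd.concat(frames, ignore_index=True))


DRUG_STATUSES = ("approved", "withdrawn")
ATC_LEVEL1 = tuple("ABCDGHJLMNPRSV")  # the 14 anatomical main groups


@dataclass(frozen=True)
class DrugRecord:
    drug_id: str
    name: str
    status: str
    target_gene_ids: frozenset[str]
    atc_level1: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if self.status not in DRUG_STATUSES:
            raise ValidationError(
                f"drug {self.drug_id}: status must be one of {DRUG_STATUSES}, "
                f"got {self.status!r}"
            )
        if not self.target_gene_ids:
            raise ValidationError(f"drug {self.drug_id}: empty target list")
        bad = set(self.atc_level1) - set(ATC_LEVEL1)
        if bad:
            raise ValidationError(
                f"drug {self.drug_id}: unknown ATC level-1 code(s) {sorted(bad)}"
            )


class REReportTable:
    """Per (drug, disease) outcome-report counts and relative efficacy.

    RE = 1 - n_ineffective / n_most_common_complaint, defined only for
    pairs with at least ``min_reports`` reports of the most common
    complaint; other pairs keep their counts but carry no RE.
    """

    COLUMNS = ("drug_id", "disease", "n_ineffective", "n_most_common_complaint")

    def __init__(self, table: pd.DataFrame, min_reports: int = 10):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"report table missing column(s): {missing}")
        table = table.copy()
        n_ineff = table["n_ineffective"].to_numpy()
        n_most = table["n_most_common_complaint"].to_numpy()
        if (n_ineff < 0).any() or (n_most < 0).any():
            raise ValidationError("report counts must be non-negative")
        if (n_ineff > n_most).any():
            raise ValidationError(
                "n_ineffective exceeds n_most_common_complaint in some row"
            )
        self.min_reports = min_reports
        eligible = n_most >= min_reports
        re = np.full(len(table), np.nan)
        with np.errstate(invalid="ignore", divide="ignore"):
            re[eligible] = 1.0 - n_ineff[eligible] / n_most[eligible]
        table["re"] = re
        self.table = table.reset_index(drop=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, REReportTable):
            return False
        cols = list(self.COLUMNS)
        a = self.table[cols].sort_values(cols).reset_index(drop=True)
        b = other.table[cols].sort_values(cols).reset_index(drop=True)
        return a.equals(b)

    def median_re_per_drug(self) -> pd.Series:
        """Median RE over a drug's RE-eligible indications."""
        sub = self.table.dropna(subset=["re"])
        return sub.groupby("drug_id")["re"].median()


class EssentialityTable:
    """Published growth-impact scores per (gene, cell line).

    Scores are negative for essential genes as published; ``per_gene``
    negates the per-gene median so that larger = more essential, and
    flags the top ``top_fraction`` as essential (ties broken by gene id).
    """

    COLUMNS = ("gene_id", "cell_line", "score")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.COLUMNS if c not in table.columns]
        if missing:
            raise ValidationError(f"essentiality table missing column(s): {missing}")
        dup = table.duplicated(["gene_id", "cell_line"])
        if dup.any():
            raise ValidationError("duplicate (gene, cell_line) essentiality rows")
        self.table = table[list(self.COLUMNS)].reset_index(drop=True)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EssentialityTable):
            return False
        cols = list(self.COLUMNS)
        a = self.table.sort_values(cols[:2]).reset_index(drop=True)
        b = other.table.sort_values(cols[:2]).reset_index(drop=True)
        return a.equals(b)

    def per_gene(self, top_fraction: float = 0.1) -> pd.DataFrame:
        """Negated median score per gene plus an ``is_essential`` flag."""
        if not (0 < top_fraction <= 1):
            raise ValidationError("top_fraction must be in (0, 1]")
        med = self.table.groupby("gene_id")["score"].median()
        neg = (-med).rename("neg_median_score")
        out = neg.to_frame()
        n_top = int(np.floor(top_fraction * len(out)))
        order = (
            out.reset_index()
            .sort_values(["neg_median_score", "gene_id"], ascending=[False, True])
            ["gene_id"]
        )
        flag = pd.Series(False, index=out.index)
        flag.loc[order[:n_top]] = True
        out["is_essential"] = flag
        return out.sort_index()
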