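"""Gene-by-sample expression profiles and their preprocessing.

The central container is :class:`ExpressionProfileSet`: an ordered gene list,
an ordered list of ``(taxon, tissue, replicate)`` sample labels, and a dense
matrix of normalized expression values.  Normalization itself (TPM / RPKM /
FPKM / TMM) happens upstream; values arriving here are assumed comparable
across samples.  Preprocessing offered below is deliberately small: log
transform, replicate collapsing, tissue/taxon subsetting, and a gene-set
filter (all genes vs. genes expressed above a threshold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError

logger = logging.getLogger("phyloexpr")

RAW = "raw"
LOG2P1 = "log2p1"


@dataclass(frozen=True, order=True)
class SampleLabel:
    """Identifies one RNA-seq sample as (taxon, tissue, replicate)."""

    taxon: str
    tissue: str
    replicate: str

    def format(self, delimiter: str = ".") -> str:
        return delimiter.join((self.taxon, self.tissue, self.replicate))

    @classmethod
    def parse(cls, text: str, delimiter: str = ".") -> "SampleLabel":
        parts = text.split(delimiter)
        if len(parts) != 3 or not all(parts):
            raise ParseError(
                f"sample column {text!r} does not follow the "
                f"taxon{delimiter}tissue{delimiter}replicate convention"
            )
        return cls(*parts)


class ExpressionProfileSet:
    """Gene x sample matrix of normalized expression with sample metadata.

    Parameters
    ----------
    genes:
        Ordered gene identifiers (unique).
    samples:
        Ordered :class:`SampleLabel` (or 3-tuples); unique.
    values:
        Array of shape ``(len(genes), len(samples))``; finite, and
        non-negative while ``transform_tag == "raw"``.
    transform_tag:
        ``"raw"`` for untransformed normalized expression, ``"log2p1"``
        once values are on the log2 analysis scale (either via
        :meth:`log_transform` or because they were generated on that scale,
        as the OU simulator does).
    """

    def __init__(
        self,
        genes: Sequence[str],
        samples: Iterable[SampleLabel | tuple],
        values,
        transform_tag: str = RAW,
    ):
        self.genes = [str(g) for g in genes]
        self.samples = [
            s if isinstance(s, SampleLabel) else SampleLabel(*map(str, s))
            for s in samples
        ]
        self.values = np.asarray(values, dtype=float)
        if transform_tag not in (RAW, LOG2P1):
            raise ValidationError(f"unknown transform_tag {transform_tag!r}")
        self.transform_tag = transform_tag
        self._validate()

    # ------------------------------------------------------------------ #

    def _validate(self) -> None:
        if self.values.ndim != 2 or self.values.shape != (
            len(self.genes),
            len(self.samples),
        ):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if len(set(self.genes)) != len(self.genes):
            dupes = sorted({g for g in self.genes if self.genes.count(g) > 1})
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        if len(set(self.samples)) != len(self.samples):
            seen: set[SampleLabel] = set()
            dupes: list[SampleLabel] = []
            for s in self.samples:
                if s in seen:
                    dupes.append(s)
                seen.add(s)
            raise ValidationError(
                f"duplicate sample labels: {[d.format() for d in dupes[:5]]}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("expression values must be finite")
        if self.transform_tag == RAW and np.any(self.values < 0):
            i, j = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"negative expression value at gene {self.genes[i]!r}, "
                f"sample {self.samples[j].format()!r}"
            )

    # -- basic views ---------------------------------------------------- #

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def taxa(self) -> list[str]:
        """Taxa in first-appearance order."""
        out: list[str] = []
        for s in self.samples:
            if s.taxon not in out:
                out.append(s.taxon)
        return out

    @property
    def tissues(self) -> list[str]:
        out: list[str] = []
        for s in self.samples:
            if s.tissue not in out:
                out.append(s.tissue)
        return out

    def to_frame(self, delimiter: str = ".") -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.genes, name="gene"),
            columns=[s.format(delimiter) for s in self.samples],
        )

    # -- preprocessing --------------------------------------------------- #

    def subset(
        self, tissue: str | None = None, taxa: Sequence[str] | None = None
    ) -> "ExpressionProfileSet":
        """Select samples by tissue and/or taxon; gene order is preserved."""
        keep = [
            j
            for j, s in enumerate(self.samples)
            if (tissue is None or s.tissue == tissue)
            and (taxa is None or s.taxon in set(taxa))
        ]
        if not keep:
            raise ValidationError(
                f"no samples match tissue={tissue!r}, taxa={taxa!r}"
            )
        return ExpressionProfileSet(
            self.genes,
            [self.samples[j] for j in keep],
            self.values[:, keep],
            self.transform_tag,
        )

    def log_transform(self, pseudocount: float = 1.0) -> "ExpressionProfileSet":
        """Return log2(x + pseudocount)-transformed profiles.

        The log scale stabilizes variances and brings the data closer to the
        Gaussian assumption of the OU model.  Transforming twice is an error.
        """
        if pseudocount <= 0:
            raise ValidationError("pseudocount must be positive")
        if self.transform_tag != RAW:
            raise ValidationError(
                "profiles are already log-transformed (transform_tag="
                f"{self.transform_tag!r})"
            )
        return ExpressionProfileSet(
            self.genes,
            self.samples,
            np.log2(self.values + pseudocount),
            LOG2P1,
        )

    def collapse_replicates(self, method: str = "mean") -> "ExpressionProfileSet":
        """Average (or median-reduce) replicates into one sample per
        (taxon, tissue); replicate label becomes ``"0"``."""
        if method not in ("mean", "median"):
            raise ValidationError(f"unknown collapse method {method!r}")
        groups: dict[tuple[str, str], list[int]] = {}
        order: list[tuple[str, str]] = []
        for j, s in enumerate(self.samples):
            key = (s.taxon, s.tissue)
            if key not in groups:
                groups[key] = []
                order.append(key)
            groups[key].append(j)
        reducer = np.mean if method == "mean" else np.median
        cols = [reducer(self.values[:, groups[k]], axis=1) for k in order]
        return ExpressionProfileSet(
            self.genes,
            [SampleLabel(t, ti, "0") for (t, ti) in order],
            np.column_stack(cols),
            self.transform_tag,
        )

    def filter_gene_set(
        self, gene_set: str = "all", threshold: float = 1.0
    ) -> "ExpressionProfileSet":
        """Keep ``all`` genes, or only ``expressed`` ones.

        ``expressed`` keeps genes whose raw value exceeds ``threshold`` in at
        least one sample of *every* taxon.  Retained genes keep their order.
        """
        if gene_set == "all":
            return self
        if gene_set != "expressed":
            raise ValidationError(f"unknown gene set {gene_set!r}")
        if self.transform_tag != RAW:
            raise ValidationError(
                "the expressed-gene filter applies to raw values; "
                "filter before log transformation"
            )
        keep = np.ones(self.n_genes, dtype=bool)
        for taxon in self.taxa:
            cols = [j for j, s in enumerate(self.samples) if s.taxon == taxon]
            keep &= (self.values[:, cols] > threshold).any(axis=1)
        n_dropped = int((~keep).sum())
        logger.info(
            "gene-set filter 'expressed' (threshold %g): kept %d, dropped %d",
            threshold,
            int(keep.sum()),
            n_dropped,
        )
        return ExpressionProfileSet(
            [g for g, k in zip(self.genes, keep) if k],
            self.samples,
            self.values[keep],
            self.transform_tag,
        )

    def taxon_matrix(
        self, tissue: str | None = None, taxa: Sequence[str] | None = None
    ) -> tuple[np.ndarray, list[str]]:
        """One column per taxon (replicates mean-collapsed) for one tissue.

        Returns ``(matrix of shape n_genes x n_taxa, taxa order)``.
        """
        sub = self if tissue is None else self.subset(tissue=tissue)
        if len(sub.tissues) != 1:
            raise ValidationError(
                f"taxon_matrix needs a single tissue; found {sub.tissues}"
            )
        sub = sub.collapse_replicates("mean")
        order = list(taxa) if taxa is not None else sub.taxa
        cols = {s.taxon: j for j, s in enumerate(sub.samples)}
        missing = [t for t in order if t not in cols]
        if missing:
            raise ValidationError(f"taxa absent from profiles: {missing}")
        return sub.values[:, [cols[t] for t in order]], order


# ---------------------------------------------------------------------- #
# file I/O


def load_expression_table(
    path, delimiter: str = ".", sep: str = "\t", transform_tag: str = RAW
) -> ExpressionProfileSet:
    """Read a genes x samples TSV into an :class:`ExpressionProfileSet`.

    The first column holds gene identifiers; every other column is named
    ``taxon<delimiter>tissue<delimiter>replicate``.  Genes with any missing
    value are dropped (complete-case policy, so every pairwise statistic
    downstream uses the same gene set); the number dropped is logged and
    stored on the returned object as ``n_dropped_genes``.  Pass
    ``transform_tag="log2p1"`` for tables already on the analysis scale
    (such as the OU simulator's output, which may contain negative values).
    """
    frame = pd.read_csv(path, sep=sep, index_col=0)
    # pandas silently renames duplicate columns; validate the raw header
    with open(path) as fh:
        raw_columns = fh.readline().rstrip("\r\n").split(sep)[1:]
    samples = [SampleLabel.parse(str(c), delimiter) for c in raw_columns]
    try:
        values = frame.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"non-numeric expression values in {path}: {exc}") from exc
    complete = ~np.isnan(values).any(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.info("dropped %d gene(s) with missing values", n_dropped)
    eps = ExpressionProfileSet(
        [str(g) for g in frame.index[complete]],
        samples,
        values[complete],
        transform_tag,
    )
    eps.n_dropped_genes = n_dropped  # type: ignore[attr-defined]
    return eps


def write_expression_table(
    expr: ExpressionProfileSet, path, delimiter: str = ".", sep: str = "\t"
) -> None:
    expr.to_frame(delimiter).to_csv(path, sep=sep)
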