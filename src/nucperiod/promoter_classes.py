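"""Promoter stratification by core promoter elements and CpG islands.

Promoters are labelled TATA+ when a TATA-box PWM hit starts at -29+-3
relative to the TSS (hit start offsets -32..-26), Inr+ when an Initiator
hit starts exactly at the TSS, Inr-DPE+ per a configured matrix and anchor
window, and CGI+ when a CpG island strictly spans the TSS.  PWMs and their
cutoffs are plain-text inputs; scanning uses additive per-position scores
(log-odds matrices are the expected scheme).

Also houses the DI-binning regression: promoters ordered by increasing
Dispersion Index are grouped into equal-size bins, CPE-positive promoters
are kept in their own bins, and mean N+1 periodicity power is regressed on
mean DI across the CPE-less bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome_io import (
    PromoterRecord,
    RelativeWindow,
    cgi_contains_tss,
)

__all__ = [
    "PWM",
    "TATA_ANCHOR_WINDOW",
    "INR_ANCHOR_WINDOW",
    "pwm_best_hit",
    "classify_promoter",
    "DIBins",
    "BinRegression",
    "bin_by_di",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}

# Hit-start anchor windows on the relative axis (half-open).
TATA_ANCHOR_WINDOW = RelativeWindow(-32, -25)   # start offsets -32..-26
INR_ANCHOR_WINDOW = RelativeWindow(0, 1)        # exactly at the TSS


@dataclass(frozen=True)
class PWM:
    """Additive position score matrix over A,C,G,T with an acceptance cutoff."""

    name: str
    matrix: np.ndarray  # (width, 4)
    cutoff: float

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"{self.name}: matrix must be (width, 4)")
        if not np.isfinite(self.cutoff):
            raise ValueError(f"{self.name}: cutoff must be finite")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def score(self, window: str) -> float:
        """Additive score of one window; any non-ACGT base scores -inf."""
        if len(window) != self.width:
            raise ValueError(f"{self.name}: window length {len(window)} != width")
        total = 0.0
        for k, base in enumerate(window.upper()):
            idx = _BASE_INDEX.get(base)
            if idx is None:
                return float("-inf")
            total += self.matrix[k, idx]
        return total

    @classmethod
    def from_counts(
        cls,
        name: str,
        counts: np.ndarray,
        cutoff: float,
        background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
        pseudocount: float = 1.0,
    ) -> "PWM":
        """Log-odds matrix from a count matrix against a background."""
        counts = np.asarray(counts, dtype=float) + pseudocount
        probs = counts / counts.sum(axis=1, keepdims=True)
        return cls(name, np.log2(probs / np.asarray(background)), cutoff)

    @classmethod
    def from_file(cls, path, name: Optional[str] = None) -> "PWM":
        """Read the plain-text PWM format.

        Header comment lines may carry ``# name=X`` and must carry
        ``# cutoff=F``; each body row holds 4 whitespace-separated scores
        (A C G T) for one position.
        """
        cutoff = None
        pwm_name = name
        rows = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    for field in line[1:].replace(",", " ").split():
                        if field.startswith("cutoff="):
                            cutoff = float(field.split("=", 1)[1])
                        elif field.startswith("name=") and pwm_name is None:
                            pwm_name = field.split("=", 1)[1]
                    continue
                vals = line.split()
                if len(vals) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 values per row")
                rows.append([float(v) for v in vals])
        if cutoff is None:
            raise ValueError(f"{path}: missing '# cutoff=' header")
        return cls(pwm_name or "pwm", np.array(rows), cutoff)

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# name={self.name} cutoff={self.cutoff:g}\n")
            fh.write("# columns: A C G T\n")
            for row in self.matrix:
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")


def pwm_best_hit(
    seq: str,
    pwm: PWM,
    search: RelativeWindow,
    seq_start_offset: int,
) -> Optional[Tuple[int, float]]:
    """Best-scoring accepted PWM hit with start offset inside `search`.

    `seq` is a transcript-oriented sequence whose base 0 sits at relative
    offset `seq_start_offset`.  Returns (start_offset, score) of the highest
    score >= cutoff, ties resolved to the smallest offset; None when no
    window passes the cutoff.
    """
    if len(search) < pwm.width:
        raise ValueError(
            f"search window [{search.start},{search.end}) narrower than "
            f"PWM width {pwm.width}"
        )
    first = search.start - seq_start_offset
    last = search.end - pwm.width - seq_start_offset  # inclusive
    if first < 0 or last + pwm.width > len(seq):
        raise ValueError("search window does not fit inside the sequence")
    best: Optional[Tuple[int, float]] = None
    for i in range(first, last + 1):
        s = pwm.score(seq[i:i + pwm.width])
        if s >= pwm.cutoff and (best is None or s > best[1]):
            best = (i + seq_start_offset, s)
    return best


def classify_promoter(
    p: PromoterRecord,
    seq: str,
    seq_start_offset: int,
    pwms: Dict[str, Tuple[PWM, RelativeWindow]],
    cgi: Optional[Dict[str, List[Tuple[int, int]]]] = None,
) -> frozenset:
    """Assign CPE/CGI class labels to one promoter.

    `pwms` maps a label (e.g. "TATA", "Inr", "InrDPE") to (matrix, anchor
    window of allowed hit-start offsets).  A label is set when a hit passes
    the cutoff inside its anchor window.  CGI+ requires an island that both
    starts before and ends after the TSS.
    """
    labels = set()
    for label, (pwm, anchor) in pwms.items():
        if pwm is None:
            raise ValueError(f"no PWM configured for label {label!r}")
        # anchor holds allowed hit-start offsets; widen to the scanned region
        region = RelativeWindow(anchor.start, anchor.end - 1 + pwm.width)
        if pwm_best_hit(seq, pwm, region, seq_start_offset) is not None:
            labels.add(label + "+")
    if cgi is not None and cgi_contains_tss(cgi, p.chrom, p.tss):
        labels.add("CGI+")
    return frozenset(labels)


# ---------------------------------------------------------------------------
# DI binning and regression


@dataclass
class BinRegression:
    slope: float
    intercept: float
    r2: float
    pvalue: float
    ci_lower: np.ndarray   # 99% CI band of predicted mean power per bin
    ci_upper: np.ndarray


@dataclass
class DIBins:
    table: pd.DataFrame            # bin, n, mean_di, mean_power, cpe
    regression: Optional[BinRegression]


def bin_by_di(
    promoters: pd.DataFrame,
    bin_size: int = 2000,
    cpe_column: str = "cpe",
    ci_level: float = 0.99,
) -> DIBins:
    """Bin promoters by increasing DI and regress mean power on mean DI.

    `promoters` needs columns ``di`` and ``power`` (mean 4-dinucleotide N+1
    power, or any periodicity summary) and optionally a boolean/label column
    naming CPE-positive promoters, which are placed in their own bins
    regardless of DI and excluded from the fit.  The last DI bin may be
    smaller than `bin_size`.
    """
    df = promoters.copy()
    if "di" not in df or "power" not in df:
        raise ValueError("promoters frame needs 'di' and 'power' columns")
    df = df[np.isfinite(df["di"])]
    if cpe_column in df:
        is_cpe = df[cpe_column].astype(bool)
    else:
        is_cpe = pd.Series(False, index=df.index)

    rows = []
    free = df[~is_cpe].sort_values(["di", "power"], kind="mergesort")
    for b, lo in enumerate(range(0, len(free), bin_size)):
        chunk = free.iloc[lo:lo + bin_size]
        rows.append(
            dict(bin=b, n=len(chunk), mean_di=chunk["di"].mean(),
                 mean_power=chunk["power"].mean(), cpe=False)
        )
    n_free_bins = len(rows)
    cpe_df = df[is_cpe]
    if len(cpe_df):
        rows.append(
            dict(bin=n_free_bins, n=len(cpe_df), mean_di=cpe_df["di"].mean(),
                 mean_power=cpe_df["power"].mean(), cpe=True)
        )
    table = pd.DataFrame(rows)

    regression = None
    fit_bins = table[~table["cpe"]]
    if len(fit_bins) < 2:
        warnings.warn("fewer than 2 DI bins: regression skipped")
    else:
        import statsmodels.api as sm

        X = sm.add_constant(fit_bins["mean_di"].to_numpy())
        model = sm.OLS(fit_bins["mean_power"].to_numpy(), X).fit()
        pred = model.get_prediction(X).conf_int(alpha=1 - ci_level)
        slope = float(model.params[1])
        pval = float(model.pvalues[1]) if len(fit_bins) > 2 else float("nan")
        regression = BinRegression(
            slope=slope,
            intercept=float(model.params[0]),
            r2=float(model.rsquared),
            pvalue=pval,
            ci_lower=pred[:, 0],
            ci_upper=pred[:, 1],
        )
    return DIBins(table, regression)
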