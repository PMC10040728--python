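"""Rater-agreement analytics for FM annotation tables.

Two trained assessors label each 5-s snippet FM+ (fidgety movements
present), FM- (absent) or NA (not assessable: the infant is fussy,
crying, drowsy, ...). Agreement on the FM+/FM- decision is quantified
after dropping every snippet that either rater called NA, by percent
agreement and by Cohen's kappa

    kappa = (p_o - p_e) / (1 - p_e),

with p_o the observed agreement and p_e the chance agreement from the
product of the marginals. The 95% CI uses the large-sample standard
error of Fleiss, Cohen & Everitt with a normal quantile. The same
machinery serves inter-rater comparisons (two assessors, one session)
and intra-rater ones (one assessor, face-visible vs face-blurred
sessions).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

LABELS = ("FM+", "FM-")
NA = "NA"
VALID_LABELS = frozenset(LABELS) | {NA}


class PairingError(ValueError):
    """Snippet sets of the two rating tables do not match."""


class UndefinedKappaError(ValueError):
    """Degenerate marginals (p_e = 1): kappa has no defined value."""


@dataclass
class RatingTable:
    """Labels of one rater in one session: snippet_id -> label."""

    labels: dict[str, str]
    rater_id: str = ""
    session: str = ""

    def __post_init__(self) -> None:
        bad = {v for v in self.labels.values()} - VALID_LABELS
        if bad:
            raise ValueError(f"labels must be in {sorted(VALID_LABELS)}, got {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_csv(cls, path: str | Path, rater_id: str | None = None,
                 session: str | None = None) -> "RatingTable":
        """Load from CSV with columns snippet_id, rater_id, session, label."""
        # keep_default_na: the literal string "NA" is a label, not a NaN
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
        required = {"snippet_id", "rater_id", "session", "label"}
        if not required.issubset(df.columns):
            raise ValueError(f"ratings CSV needs columns {sorted(required)}")
        if rater_id is not None:
            df = df[df["rater_id"] == rater_id]
        if session is not None:
            df = df[df["session"] == session]
        if df.duplicated("snippet_id").any():
            raise ValueError("multiple labels for one (snippet, rater, session)")
        return cls(
            labels=dict(zip(df["snippet_id"], df["label"])),
            rater_id=rater_id or (df["rater_id"].iloc[0] if len(df) else ""),
            session=session or (df["session"].iloc[0] if len(df) else ""),
        )

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "snippet_id": list(self.labels),
            "rater_id": self.rater_id,
            "session": self.session,
            "label": list(self.labels.values()),
        }).to_csv(path, index=False)


@dataclass
class AgreementResult:
    n_total: int
    n_na_excluded: int
    n_compared: int
    contingency: np.ndarray  # 2x2 over (FM+, FM-) x (FM+, FM-)
    percent_agreement: float
    kappa: float
    kappa_se: float
    kappa_ci95: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "n_total": self.n_total,
            "n_na_excluded": self.n_na_excluded,
            "n_compared": self.n_compared,
            "contingency": self.contingency.tolist(),
            "percent_agreement": round(self.percent_agreement, 1),
            "kappa": round(self.kappa, 2),
            "kappa_ci95": [round(v, 2) for v in self.kappa_ci95],
            "ci_method": "Fleiss-Cohen-Everitt asymptotic SE, normal quantile",
        }


def filter_assessable(a: RatingTable, b: RatingTable) -> list[tuple[str, str]]:
    """Drop snippets labeled NA by either rater; return FM+/FM- pairs."""
    if set(a.labels) != set(b.labels):
        only_a = sorted(set(a.labels) - set(b.labels))[:5]
        only_b = sorted(set(b.labels) - set(a.labels))[:5]
        raise PairingError(
            f"snippet sets differ (only in a: {only_a}, only in b: {only_b})"
        )
    return [
        (a.labels[s], b.labels[s])
        for s in a.labels
        if a.labels[s] != NA and b.labels[s] != NA
    ]


def percent_agreement(pairs: list[tuple[str, str]]) -> float:
    """100 x identical pairs / total pairs."""
    if not pairs:
        raise ValueError("cannot compute agreement on an empty pairing")
    same = sum(1 for x, y in pairs if x == y)
    return 100.0 * same / len(pairs)


def _contingency(pairs: list[tuple[str, str]]) -> np.ndarray:
    table = np.zeros((2, 2))
    idx = {lab: i for i, lab in enumerate(LABELS)}
    for x, y in pairs:
        table[idx[x], idx[y]] += 1
    return table


def kappa_from_contingency(table: np.ndarray) -> tuple[float, float]:
    """(kappa, asymptotic SE) from a square contingency table of counts.

    SE is the Fleiss-Cohen-Everitt large-sample form for kappa under
    non-independence, the standard basis for kappa CIs.
    """
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n < 2:
        raise ValueError("need at least 2 pairs")
    p = table / n
    po = float(np.trace(p))
    row, col = p.sum(axis=1), p.sum(axis=0)
    pe = float(row @ col)
    if pe >= 1.0:
        raise UndefinedKappaError(
            "both raters used a single identical category: chance agreement "
            "is 1 and kappa is undefined"
        )
    kappa = (po - pe) / (1 - pe)
    diag = np.diag(p)
    term1 = float(np.sum(diag * (1 - (row + col) * (1 - kappa)) ** 2))
    off = p * np.add.outer(col, row) ** 2  # (i,j) -> p_ij (p_.i + p_j.)^2
    term2 = (1 - kappa) ** 2 * float(off.sum() - np.sum(np.diag(off)))
    term3 = (kappa - pe * (1 - kappa)) ** 2
    var = (term1 + term2 - term3) / (n * (1 - pe) ** 2)
    return float(kappa), float(np.sqrt(max(var, 0.0)))


def cohens_kappa(pairs: list[tuple[str, str]],
                 n_total: int | None = None) -> AgreementResult:
    """Cohen's kappa with 95% CI over FM+/FM- label pairs."""
    if len(pairs) < 2:
        raise ValueError("need at least 2 pairs")
    table = _contingency(pairs)
    kappa, se = kappa_from_contingency(table)
    lo, hi = kappa - 1.96 * se, kappa + 1.96 * se
    n_total = n_total if n_total is not None else len(pairs)
    return AgreementResult(
        n_total=n_total,
        n_na_excluded=n_total - len(pairs),
        n_compared=len(pairs),
        contingency=table,
        percent_agreement=percent_agreement(pairs),
        kappa=kappa,
        kappa_se=se,
        kappa_ci95=(lo, min(hi, 1.0)),
    )


def inter_rater(a: RatingTable, b: RatingTable) -> AgreementResult:
    """Agreement between two raters in the same session, after NA filtering."""
    pairs = filter_assessable(a, b)
    res = cohens_kappa(pairs, n_total=len(a))
    return res


def intra_rater(session1: RatingTable, session2: RatingTable) -> AgreementResult:
    """One rater's agreement with themself across two sessions.

    Typically face-visible vs face-blurred; a snippet NA in either
    session is excluded, mirroring the inter-rater rule.
    """
    if session1.rater_id and session2.rater_id and session1.rater_id != session2.rater_id:
        raise ValueError(
            f"intra-rater comparison needs one rater, got "
            f"{session1.rater_id!r} and {session2.rater_id!r}"
        )
    pairs = filter_assessable(session1, session2)
    return cohens_kappa(pairs, n_total=len(session1))


def na_cross_tab(a: RatingTable, b: RatingTable) -> tuple[int, int, int]:
    """(NA count in a, NA count in b, snippets NA in both)."""
    if set(a.labels) != set(b.labels):
        raise PairingError("snippet sets differ")
    na_a = {s for s, v in a.labels.items() if v == NA}
    na_b = {s for s, v in b.labels.items() if v == NA}
    return len(na_a), len(na_b), len(na_a & na_b)
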