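"""Population statistics for a recessive-model diagnostic genotyping assay.

Once the causative allele is known, a genotyping assay is validated on
three fronts: every affected animal must be homozygous for the risk allele
and every obligate-carrier parent heterozygous (concordance); the carrier
frequency in the healthy population is estimated from heterozygote counts;
and the absence (or deficit) of risk-allele homozygotes among healthy
animals — the signature of a recessive lethal — is tested against the
Hardy-Weinberg expectation with an exact binomial lower-tail test on the
homozygote count, using the plug-in allele frequency.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy.stats import binom

ROLES = ("case", "parent", "population")
GENOTYPES = ("RR", "RA", "AA", "missing")

__all__ = [
    "ConcordanceReport",
    "HWEDeficitResult",
    "validate_assay_table",
    "concordance_check",
    "carrier_frequency",
    "deficit_homozygote_test",
]


def validate_assay_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check an assay table (columns id, role, genotype) against the closed
    role/genotype vocabularies."""
    for col in ("id", "role", "genotype"):
        if col not in table.columns:
            raise ValueError(f"assay table missing column {col!r}")
    bad_roles = set(table["role"]) - set(ROLES)
    if bad_roles:
        raise ValueError(f"unknown roles {sorted(bad_roles)}")
    bad_g = set(table["genotype"]) - set(GENOTYPES)
    if bad_g:
        raise ValueError(f"unknown genotypes {sorted(bad_g)}")
    return table


@dataclass
class ConcordanceReport:
    """Recessive-model concordance: cases must be AA, parents RA."""

    n_checked: int
    violations: list[tuple[str, str, str, str]]  # (id, role, observed, expected)
    note: str = ""

    @property
    def n_violations(self) -> int:
        return len(self.violations)

    @property
    def concordant(self) -> bool:
        return self.n_violations == 0


def concordance_check(table: pd.DataFrame) -> ConcordanceReport:
    """Flag cases that are not homozygous-alt and parents that are not
    heterozygous.  Missing genotypes are not counted as checked."""
    validate_assay_table(table)
    expected = {"case": "AA", "parent": "RA"}
    n_checked = 0
    violations = []
    for _, row in table.iterrows():
        want = expected.get(row["role"])
        if want is None or row["genotype"] == "missing":
            continue
        n_checked += 1
        if row["genotype"] != want:
            violations.append(
                (str(row["id"]), row["role"], row["genotype"], want)
            )
    note = ""
    if n_checked == 0:
        note = "no case or parent genotypes to check"
    return ConcordanceReport(n_checked, violations, note)


def carrier_frequency(table: pd.DataFrame,
                      population_role_only: bool = True) -> float:
    """Fraction of (population) samples heterozygous for the risk allele.

    Homozygous-alt animals are not carriers; missing genotypes stay in the
    denominator of the screened population only if called — they are
    dropped entirely.
    """
    validate_assay_table(table)
    sub = table
    if population_role_only:
        sub = table[table["role"] == "population"]
    sub = sub[sub["genotype"] != "missing"]
    n = len(sub)
    if n == 0:
        raise ValueError("no genotyped population samples")
    return float((sub["genotype"] == "RA").sum() / n)


@dataclass(frozen=True)
class HWEDeficitResult:
    """Exact lower-tail test for a deficit of risk-allele homozygotes."""

    n: int
    het: int
    hom: int
    q_hat: float
    expected_hom: float
    p_value: float


def deficit_homozygote_test(n: int, het: int, hom: int,
                            mid_p: bool = False) -> HWEDeficitResult:
    """Test whether ``hom`` homozygotes among ``n`` animals is fewer than
    Hardy-Weinberg predicts from the plug-in allele frequency.

    q_hat = (het + 2 hom) / 2n; under the null the homozygote count is
    Binomial(n, q_hat^2) and the p-value is the exact lower tail
    P(X <= hom).  ``mid_p`` subtracts half the point mass at the observed
    count (the mid-p variant, less conservative).
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if het < 0 or hom < 0 or het + hom > n:
        raise ValueError("het + hom must be between 0 and n")
    q = (het + 2 * hom) / (2 * n)
    p = float(binom.cdf(hom, n, q * q))
    if mid_p:
        p -= 0.5 * float(binom.pmf(hom, n, q * q))
    p = min(max(p, 0.0), 1.0)
    return HWEDeficitResult(
        n=n, het=het, hom=hom, q_hat=q, expected_hom=n * q * q, p_value=p
    )
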