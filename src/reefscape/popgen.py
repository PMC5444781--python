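"""Population-genetic statistics on codominant genotype tables.

Covers the empirical side of the analysis: GENEPOP reading/writing, site
allele frequencies, observed and Nei unbiased expected heterozygosity,
Weir & Cockerham (1984) fixation indices (F_IS, theta = F_ST) via variance
components, and the Cavalli-Sforza & Edwards chord distance used to compare
observed with simulated genetic structure.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: scale constant of the per-locus chord distance
CHORD_CONST = 2.0 * np.sqrt(2.0) / np.pi

MISSING = 0  # allele code for a missing call


@dataclass
class SiteGenotypes:
    code: str
    individuals: list  # individual names
    calls: np.ndarray  # (n_ind, n_loci, 2), allele codes, 0 = missing

    @property
    def n(self) -> int:
        return len(self.individuals)


@dataclass
class GenotypeTable:
    loci: list
    sites: list  # of SiteGenotypes

    def __post_init__(self) -> None:
        if not self.sites or not self.loci:
            raise ValueError("genotype table needs at least one site and one locus")
        for s in self.sites:
            if s.calls.shape[1:] != (len(self.loci), 2):
                raise ValueError(f"site {s.code!r} calls shape mismatch")
            if (s.calls < 0).any():
                raise ValueError("allele codes must be non-negative integers")

    @property
    def site_codes(self) -> list:
        return [s.code for s in self.sites]

    def site(self, code: str) -> SiteGenotypes:
        for s in self.sites:
            if s.code == code:
                return s
        raise KeyError(code)


# ---------------------------------------------------------------------------
# GENEPOP I/O

def read_genepop(path) -> GenotypeTable:
    """Read a GENEPOP file (2- or 3-digit allele dialect).

    The site code of each population is the name of its first individual
    (text before the comma, stripped).  ``0000`` / ``000000`` genotypes are
    missing data.
    """
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError("empty GENEPOP file")
    loci: list = []
    i = 1  # skip title line
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [x.strip() for x in lines[i].split(",") if x.strip()]
        loci.extend(chunk)
        i += 1
    if not loci:
        raise ValueError("no locus names found before first 'pop'")
    sites = []
    cur_names: list = []
    cur_calls: list = []

    def flush():
        if cur_names:
            sites.append(
                SiteGenotypes(
                    code=cur_names[0],
                    individuals=list(cur_names),
                    calls=np.array(cur_calls, dtype=int),
                )
            )

    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line:
            continue
        if line.lower() == "pop":
            flush()
            cur_names, cur_calls = [], []
            continue
        if "," not in line:
            raise ValueError(f"line {i}: expected 'name , genotypes'")
        name, geno = line.split(",", 1)
        tokens = geno.split()
        if len(tokens) != len(loci):
            raise ValueError(
                f"line {i}: {len(tokens)} genotypes for {len(loci)} loci"
            )
        row = []
        for tok in tokens:
            if not re.fullmatch(r"\d+", tok) or len(tok) not in (4, 6):
                raise ValueError(f"line {i}: malformed genotype {tok!r}")
            half = len(tok) // 2
            row.append((int(tok[:half]), int(tok[half:])))
        cur_names.append(name.strip())
        cur_calls.append(row)
    flush()
    if not sites:
        raise ValueError("no populations found")
    return GenotypeTable(loci=loci, sites=sites)


def write_genepop(table: GenotypeTable, path, title: str = "reefscape synthetic data",
                  digits: int = 3) -> None:
    """Write a GENEPOP file in the 2- or 3-digit dialect."""
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    with open(path, "w") as fh:
        fh.write(title + "\n")
        for locus in table.loci:
            fh.write(locus + "\n")
        for s in table.sites:
            fh.write("pop\n")
            for name, row in zip(s.individuals, s.calls):
                genos = " ".join(
                    f"{a1:0{digits}d}{a2:0{digits}d}" for a1, a2 in row
                )
                fh.write(f"{name} , {genos}\n")


# ---------------------------------------------------------------------------
# Allele frequencies and diversity

@dataclass
class SiteAlleleFrequencies:
    """Per site x locus allele frequencies with diploid sample sizes."""

    site_codes: list
    loci: list
    freqs: dict  # (site, locus) -> {allele: freq}
    n: dict  # (site, locus) -> diploid individuals genotyped

    def frame(self) -> pd.DataFrame:
        rows = [
            dict(site=s, locus=l, allele=a, freq=f, n=self.n[(s, l)])
            for (s, l), d in self.freqs.items()
            for a, f in d.items()
        ]
        return pd.DataFrame(rows)

    def array_for(self, sites=None) -> np.ndarray:
        """Dense (site, locus, allele) frequency array over the allele union."""
        sites = list(sites) if sites is not None else self.site_codes
        alleles = sorted({
            a for d in self.freqs.values() for a in d
        })
        pos = {a: k for k, a in enumerate(alleles)}
        out = np.zeros((len(sites), len(self.loci), len(alleles)))
        for i, s in enumerate(sites):
            for j, l in enumerate(self.loci):
                for a, f in self.freqs.get((s, l), {}).items():
                    out[i, j, pos[a]] = f
        return out


def allele_freqs(table: GenotypeTable) -> SiteAlleleFrequencies:
    """Allele frequencies per site and locus; missing calls are excluded.

    A site-locus with zero callable individuals gets an empty frequency map
    (flagged in the log).
    """
    freqs, ns = {}, {}
    for s in table.sites:
        for j, locus in enumerate(table.loci):
            calls = s.calls[:, j, :]
            called = calls[(calls != MISSING).all(axis=1)]
            n = len(called)
            ns[(s.code, locus)] = n
            if n == 0:
                freqs[(s.code, locus)] = {}
                logger.warning("site %s locus %s has no callable genotypes",
                               s.code, locus)
                continue
            vals, counts = np.unique(called.ravel(), return_counts=True)
            freqs[(s.code, locus)] = {
                int(a): c / (2.0 * n) for a, c in zip(vals, counts)
            }
    return SiteAlleleFrequencies(
        site_codes=table.site_codes, loci=list(table.loci), freqs=freqs, n=ns,
    )


def _wc_components_site(calls: np.ndarray):
    """Weir & Cockerham within-population components (b, c) per allele.

    For a single population the among-individual (b) and within-individual
    (c) variance components reduce to functions of the allele frequency and
    the observed heterozygote frequency.  Returns lists of (b, c) summed over
    alleles; None if fewer than 2 callable individuals.
    """
    called = calls[(calls != MISSING).all(axis=1)]
    n = len(called)
    if n < 2:
        return None
    alleles = np.unique(called.ravel())
    comps = []
    for a in alleles:
        p = (called == a).sum() / (2.0 * n)
        het = ((called == a).sum(axis=1) == 1).mean()
        b = (n / (n - 1.0)) * (p * (1 - p) - (2 * n - 1) / (4.0 * n) * het)
        c = het / 2.0
        comps.append((b, c))
    return comps


@dataclass
class DiversityStats:
    per_site: pd.DataFrame  # site, n_mean, H_obs, H_exp, F_IS
    per_locus: pd.DataFrame  # site, locus, n, H_obs, H_exp, F_IS


def diversity(table: GenotypeTable) -> DiversityStats:
    """Observed and Nei unbiased expected heterozygosity, and W&C F_IS.

    H_exp per locus is ``(2n / (2n - 1)) (1 - sum p^2)``; site values average
    over loci with at least two genotyped individuals.  The multilocus F_IS
    is the ratio of variance components summed over loci and alleles,
    ``1 - sum(c) / sum(b + c)``; it is NaN when no heterozygosity information
    exists (e.g. all homozygous at a monomorphic locus).
    """
    rows = []
    for s in table.sites:
        for j, locus in enumerate(table.loci):
            calls = s.calls[:, j, :]
            called = calls[(calls != MISSING).all(axis=1)]
            n = len(called)
            if n < 2:
                if n > 0:
                    logger.warning(
                        "site %s locus %s: n=%d too small for unbiased H_exp",
                        s.code, locus, n)
                continue
            h_obs = float((called[:, 0] != called[:, 1]).mean())
            _, counts = np.unique(called.ravel(), return_counts=True)
            p = counts / (2.0 * n)
            h_exp = (2.0 * n / (2.0 * n - 1.0)) * (1.0 - np.sum(p ** 2))
            comps = _wc_components_site(calls)
            bsum = sum(b for b, c in comps)
            csum = sum(c for b, c in comps)
            fis = 1.0 - csum / (bsum + csum) if (bsum + csum) != 0 else np.nan
            rows.append(dict(site=s.code, locus=locus, n=n, H_obs=h_obs,
                             H_exp=h_exp, F_IS=fis, _b=bsum, _c=csum))
    per_locus = pd.DataFrame(rows)
    site_rows = []
    for code, sub in per_locus.groupby("site", sort=False):
        bc = (sub["_b"] + sub["_c"]).sum()
        fis = 1.0 - sub["_c"].sum() / bc if bc != 0 else np.nan
        site_rows.append(dict(site=code, n_mean=sub["n"].mean(),
                              H_obs=sub["H_obs"].mean(),
                              H_exp=sub["H_exp"].mean(), F_IS=fis))
    return DiversityStats(
        per_site=pd.DataFrame(site_rows),
        per_locus=per_locus.drop(columns=["_b", "_c"]),
    )


# ---------------------------------------------------------------------------
# Weir & Cockerham theta (F_ST)

def _wc_theta_components(tables_calls, locus_idx):
    """W&C (1984) a, b, c summed over alleles for one locus across r pops."""
    data = []
    for calls in tables_calls:
        cl = calls[:, locus_idx, :]
        called = cl[(cl != MISSING).all(axis=1)]
        if len(called) > 0:
            data.append(called)
    r = len(data)
    if r < 2:
        return 0.0, 0.0, 0.0
    ns = np.array([len(d) for d in data], dtype=float)
    nbar = ns.mean()
    if nbar <= 1:
        return 0.0, 0.0, 0.0
    nc = (r * nbar - (ns ** 2).sum() / (r * nbar)) / (r - 1.0)
    alleles = np.unique(np.concatenate([d.ravel() for d in data]))
    A = B = C = 0.0
    for al in alleles:
        p = np.array([(d == al).sum() / (2.0 * len(d)) for d in data])
        h = np.array([((d == al).sum(axis=1) == 1).mean() for d in data])
        pbar = (ns * p).sum() / (r * nbar)
        s2 = (ns * (p - pbar) ** 2).sum() / ((r - 1.0) * nbar)
        hbar = (ns * h).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1.0) / r * s2 - hbar / 4.0)
            / (nbar - 1.0)
        )
        b = (nbar / (nbar - 1.0)) * (
            pbar * (1 - pbar) - (r - 1.0) / r * s2
            - (2.0 * nbar - 1.0) / (4.0 * nbar) * hbar
        )
        c = hbar / 2.0
        A += a
        B += b
        C += c
    return A, B, C


def fst_wc(table: GenotypeTable):
    """Weir & Cockerham theta: global multilocus value and pairwise matrix.

    Components are summed over alleles and loci before taking the ratio
    a / (a + b + c).  Loci monomorphic across the compared sites contribute
    zero components and thus drop out.  Pairwise values use only the two
    sites being compared.
    """
    if len(table.sites) < 2:
        raise ValueError("theta needs at least two sites")
    calls_all = [s.calls for s in table.sites]

    def theta(tables_calls):
        A = B = C = 0.0
        for j in range(len(table.loci)):
            a, b, c = _wc_theta_components(tables_calls, j)
            A += a
            B += b
            C += c
        denom = A + B + C
        return A / denom if denom != 0 else np.nan

    global_theta = theta(calls_all)
    k = len(table.sites)
    pair = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair[i, j] = pair[j, i] = theta([calls_all[i], calls_all[j]])
    return global_theta, pd.DataFrame(pair, index=table.site_codes,
                                      columns=table.site_codes)


# ---------------------------------------------------------------------------
# Chord distance

def chord_distance(freqs_x: dict, freqs_y: dict, loci=None) -> float:
    """Cavalli-Sforza & Edwards chord distance between two sites.

    ``freqs_x`` / ``freqs_y`` map locus -> {allele: frequency}.  Per locus
    ``d_l = (2 sqrt(2) / pi) sqrt(1 - sum_a sqrt(p_a q_a))`` over the union
    of alleles; the distance is the mean over loci defined in both sites.
    """
    loci = loci if loci is not None else sorted(set(freqs_x) | set(freqs_y))
    vals = []
    for l in loci:
        px = freqs_x.get(l) or {}
        qy = freqs_y.get(l) or {}
        if not px or not qy:
            logger.warning("locus %s undefined in one site; dropped", l)
            continue
        alleles = set(px) | set(qy)
        s = sum(np.sqrt(px.get(a, 0.0) * qy.get(a, 0.0)) for a in alleles)
        d2 = max(0.0, 1.0 - s)
        if d2 < 1e-12:  # identical vectors up to rounding
            d2 = 0.0
        vals.append(CHORD_CONST * np.sqrt(d2))
    if not vals:
        raise ValueError("no locus defined in both sites")
    return float(np.mean(vals))


def chord_matrix(freqs: np.ndarray) -> np.ndarray:
    """Chord-distance matrix from a dense (site, locus, allele) array.

    Frequencies must sum to 1 over the allele axis for every site x locus.
    """
    sq = np.sqrt(np.clip(freqs, 0.0, None))
    # inner[i, j, l] = sum_a sqrt(p q)
    inner = np.einsum("ila,jla->ijl", sq, sq)
    d2 = np.clip(1.0 - inner, 0.0, None)
    d2[d2 < 1e-12] = 0.0  # identical vectors: kill rounding noise before sqrt
    d = CHORD_CONST * np.sqrt(d2)
    out = d.mean(axis=2)
    out = 0.5 * (out + out.T)
    np.fill_diagonal(out, 0.0)
    return out


def site_chord_matrix(saf: SiteAlleleFrequencies, sites=None) -> pd.DataFrame:
    """Pairwise chord-distance matrix over sites of a frequency table."""
    sites = list(sites) if sites is not None else saf.site_codes
    k = len(sites)
    m = np.zeros((k, k))
    fx = {
        s: {l: saf.freqs.get((s, l), {}) for l in saf.loci} for s in sites
    }
    for i in range(k):
        for j in range(i + 1, k):
            m[i, j] = m[j, i] = chord_distance(fx[sites[i]], fx[sites[j]],
                                               loci=saf.loci)
    return pd.DataFrame(m, index=sites, columns=sites)


def standardize(matrix):
    """Scale a non-negative distance matrix so its maximum entry is 1.

    An all-zero matrix is returned unchanged (warning logged).
    """
    arr = np.asarray(matrix, dtype=float)
    off = arr[~np.eye(len(arr), dtype=bool)]
    mx = off.max() if off.size else 0.0
    if mx <= 0:
        logger.warning("distance matrix is all zero; standardization skipped")
        return matrix
    out = arr / mx
    if isinstance(matrix, pd.DataFrame):
        return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)
    return out
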