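"""Genotype and fragment-peak input/output.

Reads and writes diploid microsatellite genotype tables in the two tabular
dialects common in coral population genetics (GENEPOP and a GenAlEx-style
codominant CSV), calls mitochondrial sequence types from fragment-analysis
peak tables, and assembles the validated :class:`GenotypeDataset` the rest
of the pipeline consumes.

Mitochondrial typing follows the fragment-length convention for *Galaxea
fascicularis*: the noncoding region between *cyt* b and *nad* 2 amplifies
at ~460 bp in the mt-L (soft) type, ~170 bp in the mt-S (hard) type, and
~463 bp (a 3-bp TGG insertion) in the rarer mt-L+ type.  Colonies showing
distinct peaks of two types are heteroplasmic and typed ``both``; a minor
peak below one tenth of the main peak height is ignored.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MT_L",
    "MT_S",
    "MT_LPLUS",
    "MT_BOTH",
    "MT_UNKNOWN",
    "MITO_PEAK_SIZES",
    "Locus",
    "PeakTable",
    "GenotypeDataset",
    "GenotypeParseError",
    "call_mito_type",
    "filter_analyzable",
    "read_genepop",
    "write_genepop",
    "read_genalex_csv",
    "write_genalex_csv",
    "read_site_region_map",
    "write_site_region_map",
]

MT_L = "mtL"
MT_S = "mtS"
MT_LPLUS = "mtLplus"
MT_BOTH = "both"
MT_UNKNOWN = "unknown"

MITO_TYPES = (MT_L, MT_S, MT_LPLUS, MT_BOTH, MT_UNKNOWN)

#: Diagnostic fragment length (bp) of the cyt b -- nad 2 noncoding region.
MITO_PEAK_SIZES: dict[str, float] = {MT_L: 460.0, MT_S: 170.0, MT_LPLUS: 463.0}


class GenotypeParseError(ValueError):
    """Raised when a genotype file violates its declared layout."""


@dataclass(frozen=True)
class Locus:
    """A microsatellite locus.

    Parameters
    ----------
    name : str
        Unique locus identifier.
    repeat_motif : str, optional
        Repeat motif (e.g. ``"AC"``); informational only.
    allele_size_range : tuple of int
        Inclusive (lower, upper) bounds of plausible allele sizes in bp.
    """

    name: str
    repeat_motif: str | None = None
    allele_size_range: tuple[int, int] = (1, 999)

    def __post_init__(self) -> None:
        lo, hi = self.allele_size_range
        if lo > hi:
            raise ValueError(f"locus {self.name}: size range lower > upper")


@dataclass(frozen=True)
class PeakTable:
    """Fragment-analysis peaks for one colony.

    ``peaks`` is a sequence of ``(fragment_size_bp, height)`` pairs; heights
    are arbitrary fluorescence units and must be positive.
    """

    colony_id: str
    peaks: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.peaks) == 0:
            raise ValueError(f"{self.colony_id}: peak table is empty")
        if any(h <= 0 for _, h in self.peaks):
            raise ValueError(f"{self.colony_id}: peak heights must be > 0")


def call_mito_type(
    peaks: PeakTable | Sequence[tuple[float, float]],
    size_tolerance: float = 2.0,
    minor_ratio: float = 0.1,
) -> str:
    """Call the mitochondrial sequence type from fragment peaks.

    Each peak is matched to the nearest diagnostic size (460, 170 or 463 bp)
    within ``size_tolerance``.  If peaks of two different types co-occur the
    call is the main (tallest) peak's type when the minor type's tallest peak
    is below ``minor_ratio`` of the main height, and ``both`` when the minor
    peak is distinct (>= ``minor_ratio``).  With no recognizable peak the
    call is ``unknown``.

    The call is invariant to peak ordering and to uniform rescaling of all
    heights.
    """
    raw = peaks.peaks if isinstance(peaks, PeakTable) else peaks
    if len(raw) == 0:
        raise ValueError("peak list is empty")
    best_height: dict[str, float] = {}
    for size, height in raw:
        match, dist = None, np.inf
        for mito, target in MITO_PEAK_SIZES.items():
            d = abs(float(size) - target)
            if d <= size_tolerance and d < dist:
                match, dist = mito, d
        if match is not None:
            best_height[match] = max(best_height.get(match, 0.0), float(height))
    if not best_height:
        return MT_UNKNOWN
    ranked = sorted(best_height.items(), key=lambda kv: -kv[1])
    main_type, main_h = ranked[0]
    for other_type, other_h in ranked[1:]:
        if other_h >= minor_ratio * main_h:
            return MT_BOTH
    return main_type


# ---------------------------------------------------------------------------
# dataset container
# ---------------------------------------------------------------------------


@dataclass
class GenotypeDataset:
    """Colonies x loci diploid allele-size matrix with site/region/type labels.

    Attributes
    ----------
    loci : list of Locus
        Ordered locus definitions.
    genotypes : ndarray of int, shape (n_colonies, n_loci, 2)
        Allele sizes in bp; 0 encodes a missing allele.  Each pair is stored
        sorted ascending, and a locus is either fully called (both alleles
        > 0) or fully missing (0, 0).
    colonies : pandas.DataFrame
        One row per colony with columns ``colony_id``, ``site``, ``region``
        and ``mito_type``.
    """

    loci: list[Locus]
    genotypes: np.ndarray
    colonies: pd.DataFrame

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int64)
        if self.genotypes.ndim != 3 or self.genotypes.shape[2] != 2:
            raise ValueError("genotypes must have shape (n, n_loci, 2)")
        if self.genotypes.shape[1] != len(self.loci):
            raise ValueError("genotype matrix width != number of loci")
        names = [loc.name for loc in self.loci]
        if len(set(names)) != len(names):
            raise ValueError("duplicate locus names")
        required = {"colony_id", "site", "region", "mito_type"}
        missing_cols = required - set(self.colonies.columns)
        if missing_cols:
            raise ValueError(f"colony table lacks columns {sorted(missing_cols)}")
        if len(self.colonies) != self.genotypes.shape[0]:
            raise ValueError("colony table length != genotype matrix length")
        ids = self.colonies["colony_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"duplicate colony_id {dup!r}")
        bad = ~self.colonies["mito_type"].isin(MITO_TYPES)
        if bad.any():
            raise ValueError(
                f"invalid mito_type values: {sorted(self.colonies['mito_type'][bad].unique())}"
            )
        # every site maps to exactly one region
        site_regions = self.colonies.groupby("site")["region"].nunique()
        multi = site_regions[site_regions > 1]
        if len(multi):
            raise ValueError(f"site(s) mapped to multiple regions: {list(multi.index)}")
        self.genotypes = np.sort(self.genotypes, axis=2)
        half = (self.genotypes == 0).sum(axis=2) == 1
        if half.any():
            i, l = np.argwhere(half)[0]
            raise ValueError(
                f"colony {ids.iloc[i]!r}, locus {names[l]}: half-called genotype"
            )
        self.colonies = self.colonies.reset_index(drop=True)

    # -- basic queries ------------------------------------------------------

    @property
    def n_colonies(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    @property
    def locus_names(self) -> list[str]:
        return [loc.name for loc in self.loci]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, n_loci) mask, True where the locus is missing."""
        return (self.genotypes == 0).all(axis=2)

    def site_to_region(self) -> dict[str, str]:
        return dict(
            self.colonies.drop_duplicates("site")[["site", "region"]].itertuples(
                index=False, name=None
            )
        )

    def subset(self, index: np.ndarray | Sequence[int]) -> "GenotypeDataset":
        """Pure row subset (never alters retained genotypes)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeDataset(
            loci=list(self.loci),
            genotypes=self.genotypes[index].copy(),
            colonies=self.colonies.iloc[index].reset_index(drop=True),
        )

    def strata(
        self, keys: Sequence[str] = ("site", "mito_type")
    ) -> Iterator[tuple[tuple, "GenotypeDataset"]]:
        """Iterate (key, sub-dataset) over groups of colonies."""
        for key, grp in self.colonies.groupby(list(keys), sort=True):
            yield key, self.subset(grp.index.to_numpy())

    def counts_by_site_type(self) -> pd.DataFrame:
        """Colony counts per (region, site, mito_type) -- survey-table shape."""
        tab = (
            self.colonies.groupby(["region", "site", "mito_type"])
            .size()
            .rename("N")
            .reset_index()
        )
        return tab

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<GenotypeDataset {self.n_colonies} colonies x {self.n_loci} loci, "
            f"{self.colonies['site'].nunique()} sites>"
        )


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------


def filter_analyzable(
    dataset: GenotypeDataset, max_failed_loci: int = 2
) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Drop colonies that cannot enter the genetic analyses.

    Removes colonies typed ``both`` (heteroplasmic) or ``unknown``, and
    colonies whose multilocus genotype failed (more than ``max_failed_loci``
    loci missing).  Returns the retained dataset (a pure subset) and an
    exclusion report with one row per removed colony and its reason.
    """
    n_missing = dataset.missing_mask().sum(axis=1)
    mito = dataset.colonies["mito_type"].to_numpy()
    reasons = []
    for i in range(dataset.n_colonies):
        if mito[i] == MT_BOTH:
            reasons.append("heteroplasmic (both mitochondrial types)")
        elif mito[i] == MT_UNKNOWN:
            reasons.append("mitochondrial type undetermined")
        elif n_missing[i] > max_failed_loci:
            reasons.append(f"failed genotype ({n_missing[i]} of {dataset.n_loci} loci missing)")
        else:
            reasons.append(None)
    keep = np.array([r is None for r in reasons])
    report = pd.DataFrame(
        {
            "colony_id": dataset.colonies["colony_id"][~keep].to_numpy(),
            "site": dataset.colonies["site"][~keep].to_numpy(),
            "reason": [r for r in reasons if r is not None],
        }
    )
    if not keep.any():
        raise ValueError("filtering removed every colony")
    return dataset.subset(keep), report


# ---------------------------------------------------------------------------
# GENEPOP
# ---------------------------------------------------------------------------


def read_genepop(
    path: str | Path,
    region_map: Mapping[str, str] | None = None,
    pop_names: Sequence[str] | None = None,
) -> GenotypeDataset:
    """Read a GENEPOP (.gen) file with 2- or 3-digit allele coding.

    POP blocks map to sites.  Individual name fields of the form
    ``site|colony_id`` (as produced by :func:`write_genepop`) carry the site
    label; otherwise sites are named from ``pop_names`` or ``pop1``,
    ``pop2``, ...  ``000`` (or ``00``) alleles decode to missing.  Region
    labels come from ``region_map`` (site -> region); by default each site
    is its own region.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 3:
        raise GenotypeParseError(f"{path}: truncated GENEPOP file")
    # locus list: lines after the title until the first POP marker; a single
    # line may carry comma-separated locus names.
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().lower() != "pop":
        chunk = [s.strip() for s in lines[i].split(",") if s.strip()]
        if not chunk:
            raise GenotypeParseError(f"{path}, line {i + 1}: empty locus line")
        locus_names.extend(chunk)
        i += 1
    if i == len(lines):
        raise GenotypeParseError(f"{path}: no POP marker found")
    if not locus_names:
        raise GenotypeParseError(f"{path}: no loci declared before first POP")

    digits: int | None = None
    rows, ids, sites = [], [], []
    pop_idx = -1
    for lineno in range(i, len(lines)):
        line = lines[lineno]
        if not line.strip():
            continue
        if line.strip().lower() == "pop":
            pop_idx += 1
            continue
        if "," not in line:
            raise GenotypeParseError(
                f"{path}, line {lineno + 1}: expected 'name , genotypes'"
            )
        name, geno_part = line.split(",", 1)
        name = name.strip()
        if "|" in name:
            site, cid = name.split("|", 1)
        else:
            if pop_names is not None:
                site = pop_names[pop_idx]
            else:
                site = f"pop{pop_idx + 1}"
            cid = name
        tokens = geno_part.split()
        if len(tokens) != len(locus_names):
            raise GenotypeParseError(
                f"{path}: colony {cid!r} has {len(tokens)} genotypes, "
                f"expected {len(locus_names)}"
            )
        row = []
        for tok in tokens:
            if digits is None:
                if len(tok) not in (4, 6):
                    raise GenotypeParseError(
                        f"{path}: colony {cid!r}: genotype token {tok!r} is not "
                        "2- or 3-digit coded"
                    )
                digits = len(tok) // 2
            if len(tok) != 2 * digits or not tok.isdigit():
                raise GenotypeParseError(
                    f"{path}: colony {cid!r}: malformed genotype token {tok!r}"
                )
            row.append((int(tok[:digits]), int(tok[digits:])))
        rows.append(row)
        ids.append(cid)
        sites.append(site)
    if not rows:
        raise GenotypeParseError(f"{path}: no genotype rows")
    geno = np.array(rows, dtype=np.int64)
    # half-called entries are coerced to fully missing on decode
    half = (geno == 0).sum(axis=2) == 1
    geno[half] = 0
    region_map = dict(region_map) if region_map else {}
    colonies = pd.DataFrame(
        {
            "colony_id": ids,
            "site": sites,
            "region": [region_map.get(s, s) for s in sites],
            "mito_type": MT_UNKNOWN,
        }
    )
    loci = [Locus(name) for name in locus_names]
    return GenotypeDataset(loci=loci, genotypes=geno, colonies=colonies)


def write_genepop(dataset: GenotypeDataset, path: str | Path, digits: int = 3) -> None:
    """Write a GENEPOP file (3-digit alleles by default).

    Individual names are written as ``site|colony_id`` so that
    :func:`read_genepop` round-trips the site labels; POP blocks follow the
    dataset's site order.  Missing alleles are written as ``000``.
    """
    if digits not in (2, 3):
        raise ValueError("digits must be 2 or 3")
    limit = 10**digits
    if (dataset.genotypes >= limit).any():
        raise ValueError(f"allele sizes exceed {digits}-digit GENEPOP coding")
    path = Path(path)
    out = ["clonalpop genotype export"]
    out.extend(dataset.locus_names)
    for site in dataset.colonies["site"].unique():
        out.append("POP")
        idx = np.flatnonzero((dataset.colonies["site"] == site).to_numpy())
        for i in idx:
            cid = dataset.colonies["colony_id"].iloc[i]
            toks = [
                f"{a:0{digits}d}{b:0{digits}d}" for a, b in dataset.genotypes[i]
            ]
            out.append(f"{site}|{cid} , " + " ".join(toks))
    path.write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# GenAlEx-style CSV
# ---------------------------------------------------------------------------


def read_genalex_csv(path: str | Path) -> GenotypeDataset:
    """Read a GenAlEx-style codominant CSV.

    Layout: row 1 holds ``n_loci, n_samples, n_pops, size_pop1, ...``;
    row 2 holds a title and the population names; row 3 holds
    ``Sample, Pop, locus1, , locus2, , ...`` followed by optional metadata
    column names (``region``, ``mito_type``), which are preserved when
    present.  Genotype rows follow, one colony per row, two columns per
    locus, 0 for a missing allele.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        rows = [r for r in csv.reader(fh)]
    if len(rows) < 4:
        raise GenotypeParseError(f"{path}: truncated GenAlEx sheet")
    try:
        n_loci = int(rows[0][0])
        n_samples = int(rows[0][1])
        n_pops = int(rows[0][2])
        pop_sizes = [int(x) for x in rows[0][3 : 3 + n_pops]]
    except (ValueError, IndexError) as exc:
        raise GenotypeParseError(f"{path}: malformed count header row") from exc
    header = rows[2]
    locus_names = [header[2 + 2 * j].strip() for j in range(n_loci)]
    if any(not n for n in locus_names):
        raise GenotypeParseError(f"{path}: empty locus name in header row 3")
    meta_names = [h.strip() for h in header[2 + 2 * n_loci :] if h.strip()]
    data_rows = [r for r in rows[3:] if any(cell.strip() for cell in r)]
    if len(data_rows) != n_samples:
        raise GenotypeParseError(
            f"{path}: declared {n_samples} samples but found {len(data_rows)} rows"
        )
    if pop_sizes and sum(pop_sizes) != n_samples:
        raise GenotypeParseError(
            f"{path}: declared population sizes sum to {sum(pop_sizes)}, "
            f"not {n_samples}"
        )
    ids, sites, geno, meta = [], [], [], {m: [] for m in meta_names}
    for r in data_rows:
        ids.append(r[0].strip())
        sites.append(r[1].strip())
        try:
            pairs = [
                (int(r[2 + 2 * j] or 0), int(r[3 + 2 * j] or 0)) for j in range(n_loci)
            ]
        except (ValueError, IndexError) as exc:
            raise GenotypeParseError(
                f"{path}: colony {r[0]!r}: malformed genotype row"
            ) from exc
        geno.append(pairs)
        for k, m in enumerate(meta_names):
            col = 2 + 2 * n_loci + k
            meta[m].append(r[col].strip() if col < len(r) else "")
    geno = np.array(geno, dtype=np.int64)
    half = (geno == 0).sum(axis=2) == 1
    geno[half] = 0
    colonies = pd.DataFrame({"colony_id": ids, "site": sites})
    colonies["region"] = meta.get("region", colonies["site"])
    mito_col = meta.get("mito_type", meta.get("mito"))
    colonies["mito_type"] = mito_col if mito_col is not None else MT_UNKNOWN
    colonies["mito_type"] = colonies["mito_type"].replace("", MT_UNKNOWN)
    loci = [Locus(name) for name in locus_names]
    return GenotypeDataset(loci=loci, genotypes=geno, colonies=colonies)


def write_genalex_csv(dataset: GenotypeDataset, path: str | Path, title: str = "clonalpop export") -> None:
    """Write the GenAlEx-style codominant CSV dialect read by
    :func:`read_genalex_csv`, with ``region`` and ``mito_type`` metadata
    columns after the genotype columns."""
    path = Path(path)
    sites = list(dataset.colonies["site"].unique())
    pop_sizes = [int((dataset.colonies["site"] == s).sum()) for s in sites]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([dataset.n_loci, dataset.n_colonies, len(sites), *pop_sizes])
        w.writerow([title, "", "", *sites])
        head = ["Sample", "Pop"]
        for name in dataset.locus_names:
            head.extend([name, ""])
        head.extend(["region", "mito_type"])
        w.writerow(head)
        order = np.concatenate(
            [np.flatnonzero((dataset.colonies["site"] == s).to_numpy()) for s in sites]
        )
        for i in order:
            row = [
                dataset.colonies["colony_id"].iloc[i],
                dataset.colonies["site"].iloc[i],
            ]
            for a, b in dataset.genotypes[i]:
                row.extend([int(a), int(b)])
            row.extend(
                [dataset.colonies["region"].iloc[i], dataset.colonies["mito_type"].iloc[i]]
            )
            w.writerow(row)


# ---------------------------------------------------------------------------
# sidecar site -> region map
# ---------------------------------------------------------------------------


def read_site_region_map(path: str | Path) -> dict[str, str]:
    """Read a two-column (site, region) TSV."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2:
            raise GenotypeParseError(f"{path}, line {lineno}: expected 2 columns")
        out[parts[0]] = parts[1]
    return out


def write_site_region_map(mapping: Mapping[str, str], path: str | Path) -> None:
    Path(path).write_text(
        "".join(f"{site}\t{region}\n" for site, region in mapping.items())
    )
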