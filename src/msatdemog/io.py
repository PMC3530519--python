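"""Genepop reading/writing, QC filtering, and allele tallies.

The Genepop dialect supported: a title line, one locus name per line (or
a single comma-separated line), ``POP`` markers, and per-individual
lines ``id ,  0101 0202 ...`` with 2- or 3-digit diploid allele codes
where ``00``/``000`` is a missing allele.  Deme and sample-year
metadata travel in a sidecar TSV because the format cannot hold them.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .dataset import MISSING, GenotypeDataset, LocusDef

logger = logging.getLogger(__name__)


class GenepopParseError(ValueError):
    """Malformed Genepop input; carries the 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def _is_pop_marker(line: str) -> bool:
    return line.strip().lower() == "pop"


def read_genepop(
    path: str | Path,
    locus_defs: Optional[Sequence[LocusDef]] = None,
) -> GenotypeDataset:
    """Read a Genepop file into a :class:`GenotypeDataset`.

    Allele codes are converted to repeat units at load time using the
    affine map in each :class:`LocusDef`.  When ``locus_defs`` is not
    supplied, loci default to ``motif_length=1`` and an offset of 500
    (3-digit) or 50 (2-digit), i.e. codes are taken as raw sizes about
    a centred origin.

    Populations are labelled ``pop1``, ``pop2``, ... in POP-block order.
    """
    lines = Path(path).read_text().splitlines()
    if not lines:
        raise GenepopParseError(1, "empty file")
    # locate first POP marker; everything between title and it is locus names
    pop_line = next((i for i, l in enumerate(lines) if _is_pop_marker(l)), None)
    if pop_line is None or pop_line < 2:
        raise GenepopParseError(
            1 if pop_line is None else pop_line + 1,
            "malformed header: need title line, locus names, then POP",
        )
    locus_names: list[str] = []
    for raw in lines[1:pop_line]:
        raw = raw.strip()
        if not raw:
            continue
        if "," in raw:
            locus_names.extend(t.strip() for t in raw.split(",") if t.strip())
        else:
            locus_names.append(raw)
    if not locus_names:
        raise GenepopParseError(2, "no locus names before first POP")

    coding: Optional[int] = None
    pops: list[list[tuple[str, list[str], int]]] = []
    for lineno0 in range(pop_line, len(lines)):
        line = lines[lineno0]
        if not line.strip():
            continue
        if _is_pop_marker(line):
            pops.append([])
            continue
        if "," not in line:
            raise GenepopParseError(lineno0 + 1, "individual line lacks ','")
        ind_id, _, geno = line.partition(",")
        tokens = geno.split()
        if len(tokens) != len(locus_names):
            raise GenepopParseError(
                lineno0 + 1,
                f"expected {len(locus_names)} genotypes, found {len(tokens)}",
            )
        for tok in tokens:
            if len(tok) not in (4, 6) or not tok.isdigit():
                raise GenepopParseError(
                    lineno0 + 1, f"odd or non-numeric allele code {tok!r}"
                )
            width = len(tok) // 2
            if coding is None:
                coding = width
            elif width != coding:
                raise GenepopParseError(
                    lineno0 + 1,
                    f"inconsistent code width: saw both {coding}- and "
                    f"{width}-digit codes",
                )
        pops[-1].append((ind_id.strip(), tokens, lineno0 + 1))

    assert coding is not None
    if locus_defs is None:
        default_offset = 500 if coding == 3 else 50
        loci = [
            LocusDef(name, motif_length=1, coding=coding, offset=default_offset)
            for name in locus_names
        ]
    else:
        loci = list(locus_defs)
        if [l.name for l in loci] != locus_names:
            # allow user defs in file order with differing labels only if count matches
            if len(loci) != len(locus_names):
                raise ValueError(
                    f"{len(loci)} locus_defs supplied for {len(locus_names)} loci"
                )
        for l in loci:
            if l.coding != coding:
                raise ValueError(
                    f"locus {l.name}: coding {l.coding} but file uses {coding}-digit codes"
                )

    individuals: list[str] = []
    population: list[str] = []
    rows: list[np.ndarray] = []
    used: Counter = Counter()
    for p_idx, block in enumerate(pops):
        label = f"pop{p_idx + 1}"
        for ind_id, tokens, lineno in block:
            used[ind_id] += 1
            if used[ind_id] > 1:
                ind_id = f"{ind_id}.{used[ind_id]}"
            row = np.full((len(loci), 2), MISSING)
            for j, tok in enumerate(tokens):
                a, b = int(tok[:coding]), int(tok[coding:])
                if a == 0 or b == 0:
                    continue  # half-missing treated as fully missing
                try:
                    row[j, 0] = loci[j].code_to_size(a)
                    row[j, 1] = loci[j].code_to_size(b)
                except ValueError as e:
                    raise GenepopParseError(lineno, str(e)) from e
            individuals.append(ind_id)
            population.append(label)
            rows.append(row)

    return GenotypeDataset(
        individuals=individuals,
        loci=loci,
        calls=np.stack(rows) if rows else np.empty((0, len(loci), 2)),
        population=np.array(population, dtype=object),
    )


def write_genepop(
    dataset: GenotypeDataset, path: str | Path, title: str = "msatdemog export"
) -> None:
    """Write a dataset as canonical Genepop (one locus name per line).

    Individuals are grouped into POP blocks by population label in order
    of first appearance; read-back recovers the same calls, missingness
    and block structure.
    """
    if dataset.n_individuals == 0 or not dataset.populations():
        raise ValueError("cannot write a dataset with no populations")
    out = [title]
    out.extend(l.name for l in dataset.loci)
    for pop in dataset.populations():
        out.append("POP")
        for i in np.flatnonzero(dataset.population == pop):
            codes = []
            for j, locus in enumerate(dataset.loci):
                a, b = dataset.calls[i, j]
                if np.isnan(a):
                    z = "0" * locus.coding
                    codes.append(z + z)
                else:
                    codes.append(
                        f"{locus.size_to_code(int(a)):0{locus.coding}d}"
                        f"{locus.size_to_code(int(b)):0{locus.coding}d}"
                    )
            out.append(f"{dataset.individuals[i]} ,  " + " ".join(codes))
    Path(path).write_text("\n".join(out) + "\n")


# ----------------------------------------------------------------------
# sidecar metadata


def write_metadata(dataset: GenotypeDataset, path: str | Path) -> None:
    """Write the sidecar TSV (individual, population, deme, year)."""
    df = pd.DataFrame(
        {
            "individual": dataset.individuals,
            "population": dataset.population,
            "deme": dataset.deme if dataset.deme is not None else "",
            "year": dataset.sample_year if dataset.sample_year is not None else "",
        }
    )
    df.to_csv(path, sep="\t", index=False)


def attach_metadata(dataset: GenotypeDataset, path: str | Path) -> GenotypeDataset:
    """Attach sidecar TSV metadata (deme, year, optional population relabel)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual": str})
    df = df.set_index("individual")
    missing = [i for i in dataset.individuals if i not in df.index]
    if missing:
        raise KeyError(f"sidecar lacks rows for individuals: {missing[:5]} ...")
    sub = df.loc[dataset.individuals]

    def col(name):
        if name not in sub.columns:
            return None
        vals = sub[name]
        if vals.isna().all() or (vals.astype(str).str.strip() == "").all():
            return None
        return vals.to_numpy()

    pop = col("population")
    return GenotypeDataset(
        individuals=dataset.individuals,
        loci=dataset.loci,
        calls=dataset.calls,
        population=pop if pop is not None else dataset.population,
        deme=col("deme"),
        sample_year=col("year"),
    )


# ----------------------------------------------------------------------
# QC and tallies


def filter_individuals(dataset: GenotypeDataset, min_loci: int) -> GenotypeDataset:
    """Keep individuals typed at ``min_loci`` or more loci.

    The standard QC step for mixed-quality (museum + noninvasive)
    samples: an individual enters the analysis only with a genotype at a
    minimum number of loci.
    """
    if not 0 <= min_loci <= dataset.n_loci:
        raise ValueError(f"min_loci must be in [0, {dataset.n_loci}]")
    typed = dataset.typed_loci_per_individual()
    keep = typed >= min_loci
    dropped = [ind for ind, k in zip(dataset.individuals, keep) if not k]
    if dropped:
        logger.info(
            "filter_individuals(min_loci=%d): removed %d of %d individuals: %s",
            min_loci,
            len(dropped),
            dataset.n_individuals,
            ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""),
        )
    return dataset.subset(keep)


def allele_counts(
    dataset: GenotypeDataset,
    population: Optional[str] = None,
    deme: Optional[str] = None,
) -> list[Counter]:
    """Per-locus allele-size tallies for one group (or the whole dataset).

    Missing calls contribute nothing; counts at a locus sum to twice the
    number of individuals typed there.
    """
    ds = dataset
    if population is not None or deme is not None:
        ds = dataset.select(population=population, deme=deme)
    if ds.n_individuals == 0:
        raise ValueError("selected group is empty")
    return [Counter(ds.sizes_at_locus(j).tolist()) for j in range(ds.n_loci)]
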