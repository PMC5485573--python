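"""Readers and writers for genotype panels.

Formats:

* PLINK PED/MAP text. MAP columns: chromosome, SNP id, genetic distance
  (written as 0), 1-based bp position. PED columns: family id, individual
  id, father, mother, sex, phenotype, then two allele tokens per SNP.
  Alleles are coded A/B (dose = number of B alleles), missing calls as
  ``0 0``, and the phenotype column carries 2 = carrier, 1 = non-carrier.
* CSV genotype matrix: header row of SNP ids, first column the individual
  id, missing as an empty field; labels in a two-column CSV.
* Flat key/value YAML for :class:`~phenonoise.simdata.SimulationConfig`.

Round-trips are exact: ``read(write(panel)) == panel``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simdata import CarrierLabels, GenotypeMatrix, SimulationConfig

__all__ = [
    "write_plink",
    "read_plink",
    "write_genotype_csv",
    "read_genotype_csv",
    "write_labels_csv",
    "read_labels_csv",
    "write_config",
    "read_config",
]

_DOSE_TO_ALLELES = {0.0: ("A", "A"), 1.0: ("A", "B"), 2.0: ("B", "B")}


class PlinkParseError(ValueError):
    """Malformed PED/MAP content; message carries the 1-based line number."""


def write_plink(g: GenotypeMatrix, labels: CarrierLabels, prefix: str | Path) -> None:
    """Write ``<prefix>.ped`` and ``<prefix>.map``."""
    if len(labels) != g.n_individuals:
        raise ValueError("labels length does not match panel")
    prefix = Path(prefix)
    with open(prefix.with_suffix(".map"), "w") as fh:
        for row in g.locus_table.itertuples(index=False):
            fh.write(f"{row.chromosome}\t{row.id}\t0\t{row.position}\n")
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, ind in enumerate(g.individual_ids):
            tokens = [str(ind), str(ind), "0", "0", "0",
                      "2" if labels.values[i] else "1"]
            for v in g.values[i]:
                a, b = ("0", "0") if np.isnan(v) else _DOSE_TO_ALLELES[v]
                tokens.append(a)
                tokens.append(b)
            fh.write(" ".join(tokens) + "\n")


def read_plink(prefix: str | Path) -> tuple[GenotypeMatrix, CarrierLabels]:
    """Read a ``<prefix>.ped`` / ``<prefix>.map`` pair."""
    prefix = Path(prefix)
    ids, chroms, positions = [], [], []
    with open(prefix.with_suffix(".map")) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkParseError(
                    f"{prefix.with_suffix('.map')}:{lineno}: expected 4 columns, "
                    f"got {len(parts)}")
            chroms.append(parts[0])
            ids.append(parts[1])
            positions.append(int(parts[3]))
    m = len(ids)
    locus_table = pd.DataFrame(
        {"id": ids, "chromosome": chroms,
         "position": np.asarray(positions, dtype=np.int64)})

    rows, individual_ids, labels = [], [], []
    ped = prefix.with_suffix(".ped")
    with open(ped) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6 or (len(parts) - 6) % 2:
                raise PlinkParseError(
                    f"{ped}:{lineno}: odd allele count "
                    f"({len(parts) - 6} genotype tokens)")
            if (len(parts) - 6) // 2 != m:
                raise PlinkParseError(
                    f"{ped}:{lineno}: {(len(parts) - 6) // 2} SNPs, "
                    f"MAP declares {m}")
            individual_ids.append(parts[1])
            pheno = parts[5]
            if pheno not in ("1", "2"):
                raise PlinkParseError(
                    f"{ped}:{lineno}: phenotype must be 1 or 2, got {pheno!r}")
            labels.append(1 if pheno == "2" else 0)
            doses = np.empty(m, dtype=np.float64)
            for j in range(m):
                a, b = parts[6 + 2 * j], parts[7 + 2 * j]
                if a == "0" or b == "0":
                    if a != b:
                        raise PlinkParseError(
                            f"{ped}:{lineno}: half-missing call at SNP {j + 1}")
                    doses[j] = np.nan
                elif a in "AB" and b in "AB":
                    doses[j] = (a == "B") + (b == "B")
                else:
                    raise PlinkParseError(
                        f"{ped}:{lineno}: unknown allele {a!r}/{b!r} at SNP {j + 1}")
            rows.append(doses)
    g = GenotypeMatrix(np.vstack(rows), locus_table,
                       np.asarray(individual_ids, dtype=object))
    return g, CarrierLabels(np.asarray(labels, dtype=np.int8))


def write_genotype_csv(g: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(g.values, index=pd.Index(g.individual_ids, name="individual"),
                      columns=g.locus_ids)
    df.to_csv(path, float_format="%.0f")


def read_genotype_csv(path: str | Path) -> GenotypeMatrix:
    """Read a CSV dose matrix; the map is synthesised from column order."""
    df = pd.read_csv(path, index_col=0)
    m = df.shape[1]
    locus_table = pd.DataFrame({
        "id": df.columns.astype(str),
        "chromosome": ["0"] * m,
        "position": np.arange(1, m + 1, dtype=np.int64),
    })
    return GenotypeMatrix(df.to_numpy(dtype=np.float64), locus_table,
                          df.index.to_numpy(dtype=object).astype(str))


def write_labels_csv(labels: CarrierLabels, individual_ids, path: str | Path) -> None:
    pd.DataFrame({"individual": individual_ids,
                  "carrier": labels.values}).to_csv(path, index=False)


def read_labels_csv(path: str | Path) -> CarrierLabels:
    df = pd.read_csv(path)
    return CarrierLabels(df["carrier"].to_numpy(dtype=np.int8))


def write_config(config: SimulationConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_flat_dict(), fh, sort_keys=False)


def read_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_flat_dict(yaml.safe_load(fh))
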