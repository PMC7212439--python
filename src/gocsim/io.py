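"""Plain-text and HDF5 exports.

Everything a downstream pedigree/genotype tool commonly consumes: a locus
map, a three-column pedigree, dosage matrices, phased VCF, lower-triangle
relationship matrices, GEBV tables and mating plans — plus an HDF5 container
for founder pools so an expensive founder run can be reused.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .founder import FounderOutput, TraitModel
from .genome import GenomeSpec

__all__ = [
    "export_locus_map",
    "export_pedigree",
    "export_dosage_matrix",
    "export_vcf",
    "export_grm_lower_triangle",
    "export_gebv_table",
    "export_mating_plan",
    "save_founder",
    "load_founder",
]


def export_locus_map(founder: FounderOutput, path) -> None:
    """Tab-delimited locus map: chromosome, position (cM), class, base
    frequency, additive effect (0 for markers)."""
    t = founder.loci_table.copy()
    eff = pd.Series(0.0, index=t["locus"])
    eff.loc[founder.trait.qtl_ids] = founder.trait.effects
    t["effect"] = eff.to_numpy()
    t.to_csv(path, sep="\t", index=False)


def export_pedigree(pedigree: dict, path) -> None:
    """Three-column pedigree (id, sire, dam), 0 for unknown parents."""
    rows = [
        (a, s if s is not None else 0, d if d is not None else 0)
        for a, (s, d) in sorted(pedigree.items())
    ]
    pd.DataFrame(rows, columns=["id", "sire", "dam"]).to_csv(
        path, sep="\t", index=False
    )


def export_dosage_matrix(pop, animals, loci: np.ndarray, path) -> None:
    """Tab-delimited 0/1/2 dosage matrix, one row per animal."""
    d = pop.dosage_matrix(animals, loci)
    df = pd.DataFrame(d, columns=[f"locus_{l}" for l in loci])
    df.insert(0, "id", [a.id for a in animals])
    df.to_csv(path, sep="\t", index=False)


def export_vcf(spec: GenomeSpec, animals, loci: np.ndarray, path) -> None:
    """Minimal biallelic phased VCF of the given animals at the given loci.

    Physical positions are the cM grid positions scaled by 1e4 (so the
    equidistant candidate grid maps to integer coordinates).
    """
    loci = np.asarray(loci, dtype=np.int64)
    chroms = spec.locus_chrom(loci) + 1
    pos = np.round(spec.locus_pos_cM(loci) * 1e4).astype(np.int64)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for c in range(spec.n_chromosomes):
            fh.write(f"##contig=<ID={c + 1}>\n")
        names = "\t".join(f"ind{a.id}" for a in animals)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{names}\n")
        carry = []
        for a in animals:
            flags = []
            for h in a.hap:
                idx = np.searchsorted(loci, h)
                ok = idx < loci.size
                ok[ok] = loci[idx[ok]] == h[ok]
                f = np.zeros(loci.size, dtype=np.int8)
                f[idx[ok]] = 1
                flags.append(f)
            carry.append(flags)
        for j, (c, p, l) in enumerate(zip(chroms, pos, loci)):
            gts = "\t".join(f"{carry[i][0][j]}|{carry[i][1][j]}" for i in range(len(animals)))
            fh.write(f"{c}\t{p}\tlocus_{l}\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def export_grm_lower_triangle(matrix, path) -> None:
    """Whitespace-delimited lower triangle: row id, col id, value."""
    ids = matrix.animal_ids
    with open(path, "w") as fh:
        for i in range(ids.size):
            for j in range(i + 1):
                fh.write(f"{ids[i]} {ids[j]} {matrix.values[i, j]:.10g}\n")


def export_gebv_table(fit, pop, path) -> None:
    """Tab-delimited GEBV table: id, generation, sex, gebv, has phenotype."""
    rows = []
    for a_id, g in zip(fit.animal_ids, fit.gebv):
        a = pop[int(a_id)]
        rows.append((a.id, a.generation, a.sex, g, int(a.phenotype is not None)))
    pd.DataFrame(
        rows, columns=["id", "generation", "sex", "gebv", "phenotyped"]
    ).to_csv(path, sep="\t", index=False)


def export_mating_plan(solution, pairs, path) -> None:
    """Tab-delimited mating plan: mating index, sire id, dam id, offspring."""
    ids = solution.problem.candidate_ids
    n = solution.problem.offspring_per_mating
    rows = [(k, ids[s], ids[d], n) for k, (s, d) in enumerate(pairs)]
    pd.DataFrame(rows, columns=["mating", "sire", "dam", "n_offspring"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# founder container


def save_founder(founder: FounderOutput, path) -> None:
    """HDF5 container with the chromosome pools, locus table and trait."""
    spec = founder.spec
    with h5py.File(path, "w") as f:
        g = f.create_group("spec")
        for k in (
            "n_chromosomes",
            "chrom_length_cM",
            "loci_per_cM",
            "qtl_fraction",
            "mutation_rate",
            "ibd_loci_per_cM",
        ):
            g.attrs[k] = getattr(spec, k)
        pools = f.create_group("pools")
        for c, pool in enumerate(founder.pools):
            gc = pools.create_group(str(c))
            for j, h in enumerate(pool):
                gc.create_dataset(str(j), data=h)
        t = founder.loci_table
        lt = f.create_group("loci")
        for col in ("locus", "chrom", "pos_cM", "freq"):
            lt.create_dataset(col, data=t[col].to_numpy())
        lt.create_dataset(
            "klass", data=np.array(t["klass"], dtype=h5py.string_dtype())
        )
        tr = f.create_group("trait")
        tr.create_dataset("qtl_ids", data=founder.trait.qtl_ids)
        tr.create_dataset("effects", data=founder.trait.effects)
        tr.attrs["scale_applied"] = founder.trait.scale_applied


def load_founder(path) -> FounderOutput:
    with h5py.File(path, "r") as f:
        spec = GenomeSpec(
            n_chromosomes=int(f["spec"].attrs["n_chromosomes"]),
            chrom_length_cM=float(f["spec"].attrs["chrom_length_cM"]),
            loci_per_cM=float(f["spec"].attrs["loci_per_cM"]),
            qtl_fraction=float(f["spec"].attrs["qtl_fraction"]),
            mutation_rate=float(f["spec"].attrs["mutation_rate"]),
            ibd_loci_per_cM=float(f["spec"].attrs["ibd_loci_per_cM"]),
        )
        pools = []
        for c in range(spec.n_chromosomes):
            gc = f["pools"][str(c)]
            pools.append(
                [gc[str(j)][...].astype(np.int64) for j in range(len(gc))]
            )
        table = pd.DataFrame(
            {
                "locus": f["loci/locus"][...],
                "chrom": f["loci/chrom"][...],
                "pos_cM": f["loci/pos_cM"][...],
                "klass": [s.decode() for s in f["loci/klass"][...]],
                "freq": f["loci/freq"][...],
            }
        )
        trait = TraitModel(
            f["trait/qtl_ids"][...],
            f["trait/effects"][...],
            float(f["trait"].attrs["scale_applied"]),
        )
    return FounderOutput(spec, pools, table, trait)
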