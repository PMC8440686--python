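"""Seedable synthetic cohort + knowledge-table generator.

Emulates the statistical structure the reanalysis engine assumes: a cohort of
families (trio / singleton / other, default mix 28/68/4 percent) submitted by
four disease networks, per-family pre-annotated VCFs over a small toy genome
(two 10-Mb autosomes, a 5-Mb X and the mitochondrial contig — large enough to
exercise run-of-homozygosity logic, small enough to simulate in seconds),
matching knowledge tables (pathogenicity assertions with controlled
first-assertion years, population frequencies, gene-disease associations,
constraint scores, ACMG classes, an HPO mini-ontology plus term-to-gene map),
network gene panels, an optional CNV file and a truth table.

Each family is assigned one causative-variant model (autosomal dominant
de novo or inherited, autosomal recessive homozygous — optionally inside a
>=1.2 Mb homozygous stretch — or compound het, X-linked, mitochondrial,
mosaic, a lone heterozygous hit in a recessive gene, or none). Planted
variants carry pathogenic/likely-pathogenic assertions, rare frequencies and
panel-gene membership, so the first-round preset is guaranteed to see them;
negative-control families carry either nothing or a "decoy" pathogenic
variant that deliberately fails the rarity filter. Background genotypes are
Hardy-Weinberg draws with Mendelian transmission inside each family, with
allele frequencies drawn log-uniformly over [1e-5, 0.5] so the frequency
filters have bite.

Everything is deterministic under the spec seed: running the generator twice
with the same spec yields byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

GENOME = {"1": 10_000_000, "2": 10_000_000, "X": 5_000_000, "MT": 16_569}
AUTOSOMES = ("1", "2")
AUTOSOME_LENGTH = sum(GENOME[c] for c in AUTOSOMES)
ERNS = ("ITHACA", "RND", "euroNMD", "GENTURIS")
#: submitting-network weights (approximate real cohort composition)
ERN_WEIGHTS = (0.334, 0.464, 0.140, 0.062)

MODELS = (
    "AD-denovo", "AD-inherited", "AR-hom", "AR-hom-in-ROH", "AR-comphet",
    "XL", "MT", "mosaic", "het-AR-only", "none",
)

_CONSEQUENCES = ["missense_variant", "stop_gained", "splice_acceptor_variant",
                 "frameshift_variant", "synonymous_variant", "intron_variant"]
_CONSEQ_W = [0.35, 0.10, 0.05, 0.10, 0.20, 0.20]

_GENE_BLOCK = 200_000


@dataclass
class SimSpec:
    """Study-condition parameters of one synthetic cohort."""

    seed: int
    n_families: int = 200
    structure_mix: tuple[float, float, float] = (0.28, 0.68, 0.04)  # trio/singleton/other
    n_background_sites: int = 1500
    planted_model_mix: dict[str, float] = field(default_factory=lambda: {
        "AD-denovo": 0.20, "AD-inherited": 0.15, "AR-hom": 0.10,
        "AR-hom-in-ROH": 0.08, "AR-comphet": 0.12, "XL": 0.06, "MT": 0.02,
        "mosaic": 0.02, "het-AR-only": 0.10, "none": 0.15,
    })
    background_af_range: tuple[float, float] = (1e-5, 0.5)
    planted_af_range: tuple[float, float] = (1e-5, 5e-3)
    decoy_af: float = 0.05          # population AF of decoys: fails the <0.01 filter
    decoy_rate: float = 0.5         # fraction of "none" families that get a decoy
    background_plp_rate: float = 0.0
    gene_year_weights: dict[str, float] = field(default_factory=lambda: {
        ">=2017": 0.13, "2015-2016": 0.09, "2010-2014": 0.31, "<2010": 0.47})
    variant_year_weights: dict[str, float] = field(default_factory=lambda: {
        ">=2017": 0.39, "2015-2016": 0.21, "2010-2014": 0.31, "<2010": 0.09})
    missing_rate: float = 0.01
    roh_flank_bp: int = 1_500_000   # homozygous flank either side of an in-ROH variant
    male_fraction: float = 0.557

    def __post_init__(self) -> None:
        if abs(sum(self.structure_mix) - 1.0) > 1e-9:
            raise ValueError("structure_mix must sum to 1")
        if abs(sum(self.planted_model_mix.values()) - 1.0) > 1e-9:
            raise ValueError("planted_model_mix must sum to 1")
        unknown = set(self.planted_model_mix) - set(MODELS)
        if unknown:
            raise ValueError(f"unknown planted models: {sorted(unknown)}")


# ---------------------------------------------------------------------------
# gene map and panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimGene:
    symbol: str
    contig: str
    start: int
    end: int
    mode: Optional[str]  # AD | AR | XL | MT | None (background)


def _build_genes() -> list[SimGene]:
    ad = [f"D{i:03d}" for i in range(1, 13)]
    ar = [f"D{i:03d}" for i in range(13, 27)]
    bg = [f"B{i:03d}" for i in range(1, 61)]
    autosomal = [(g, "AD") for g in ad] + [(g, "AR") for g in ar] + [(g, None) for g in bg]
    genes = []
    for i, (symbol, mode) in enumerate(autosomal):
        contig = AUTOSOMES[i % 2]
        block = i // 2
        start = block * _GENE_BLOCK + 1
        genes.append(SimGene(symbol, contig, start, start + _GENE_BLOCK - 1, mode))
    for i in range(4):
        start = i * 1_250_000 + 1
        genes.append(SimGene(f"X{i + 1:03d}", "X", start, start + _GENE_BLOCK - 1, "XL"))
    genes.append(SimGene("MTG1", "MT", 1, GENOME["MT"], "MT"))
    return genes


def _build_panels(genes: list[SimGene]) -> dict[str, list[str]]:
    ad = [g.symbol for g in genes if g.mode == "AD"]
    ar = [g.symbol for g in genes if g.mode == "AR"]
    xl = [g.symbol for g in genes if g.mode == "XL"]
    panels: dict[str, list[str]] = {}
    ar_split = [ar[0:4], ar[4:8], ar[8:11], ar[11:14]]
    for i, ern in enumerate(ERNS):
        panels[ern] = sorted(ad[3 * i:3 * i + 3] + ar_split[i] + [xl[i], "MTG1"])
    return panels


# ---------------------------------------------------------------------------
# mini HPO ontology
# ---------------------------------------------------------------------------

def _build_ontology() -> tuple[dict[str, list[str]], list[str]]:
    """Returns (term -> parent list, leaf terms). Synthetic ids, 4 levels:
    root, phenotypic-abnormality, 8 system terms, 32 leaves, plus an excluded
    inheritance branch."""
    parents: dict[str, list[str]] = {"HP:0000001": [], "HP:0000118": ["HP:0000001"],
                                     "HP:0000005": ["HP:0000001"],
                                     "HP:0000006": ["HP:0000005"]}
    leaves = []
    for s in range(8):
        system = f"HP:{1000 + s:07d}"
        parents[system] = ["HP:0000118"]
        for l in range(4):
            leaf = f"HP:{2000 + 4 * s + l:07d}"
            parents[leaf] = [system]
            leaves.append(leaf)
    return parents, leaves


def _write_obo(parents: dict[str, list[str]], path: Path) -> None:
    lines = ["format-version: 1.2", "ontology: hp-sim", ""]
    for term in parents:
        lines.append("[Term]")
        lines.append(f"id: {term}")
        lines.append(f"name: synthetic term {term}")
        for p in parents[term]:
            lines.append(f"is_a: {p} ! synthetic term {p}")
        lines.append("")
    path.write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# sites and genotypes
# ---------------------------------------------------------------------------

_BASES = ("A", "C", "G", "T")


@dataclass
class SimSite:
    contig: str
    pos: int
    ref: str
    alt: str
    gene: str
    consequence: str
    af: float
    planted_by: Optional[str] = None  # family id, for planted/decoy sites
    #: member experiment id -> (genotype string, allelic fraction or None)
    planted_genotypes: dict[str, tuple[str, Optional[float]]] = field(default_factory=dict)

    @property
    def key_string(self) -> str:
        return f"{self.contig}:{self.pos}:{self.ref}:{self.alt}"


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _draw_year(rng: np.random.Generator, weights: dict[str, float]) -> int:
    bins = list(weights)
    b = rng.choice(bins, p=np.array([weights[x] for x in bins]))
    lo, hi = {">=2017": (2017, 2019), "2015-2016": (2015, 2016),
              "2010-2014": (2010, 2014), "<2010": (1990, 2009)}[b]
    return int(rng.integers(lo, hi + 1))


def _snv(rng: np.random.Generator) -> tuple[str, str]:
    ref = _BASES[rng.integers(4)]
    alt = _BASES[rng.integers(4)]
    while alt == ref:
        alt = _BASES[rng.integers(4)]
    return ref, alt


@dataclass
class SimFamily:
    family_id: str
    structure: str  # trio | singleton | other
    model: str
    ern: str
    index_sex: str  # male | female

    @property
    def index_id(self) -> str:
        return f"{self.family_id}-P"

    @property
    def member_ids(self) -> list[str]:
        if self.structure == "trio":
            return [self.index_id, f"{self.family_id}-F", f"{self.family_id}-M"]
        if self.structure == "other":
            return [self.index_id, f"{self.family_id}-M"]
        return [self.index_id]

    @property
    def father_id(self) -> Optional[str]:
        return f"{self.family_id}-F" if self.structure == "trio" else None

    @property
    def mother_id(self) -> Optional[str]:
        return f"{self.family_id}-M" if self.structure in ("trio", "other") else None


def _required_mode(model: str) -> Optional[str]:
    if model.startswith("AD") or model == "mosaic":
        return "AD"
    if model.startswith("AR") or model == "het-AR-only":
        return "AR"
    if model == "XL":
        return "XL"
    if model == "MT":
        return "MT"
    return None


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

@dataclass
class SimResult:
    out_dir: Path
    truth: pd.DataFrame
    families: pd.DataFrame
    config_path: Path


def simulate_cohort(spec: SimSpec, out_dir: str | Path) -> SimResult:
    """Write a self-contained fixture directory (VCFs, PED, phenotype JSON,
    knowledge TSVs, panels, ontology, CNV BED, truth table, run config)."""
    rng = np.random.default_rng(spec.seed)
    out = Path(out_dir)
    for sub in ("vcfs", "knowledge", "panels", "ontology", "cnv"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    genes = _build_genes()
    genes_by_symbol = {g.symbol: g for g in genes}
    panels = _build_panels(genes)
    ont_parents, leaves = _build_ontology()

    # term -> gene map: two leaf terms per disease gene
    disease_genes = [g for g in genes if g.mode]
    gene_terms: dict[str, list[str]] = {}
    for i, g in enumerate(disease_genes):
        gene_terms[g.symbol] = [leaves[(2 * i) % len(leaves)],
                                leaves[(2 * i + 1) % len(leaves)]]

    # --- families -----------------------------------------------------------
    structures = rng.choice(["trio", "singleton", "other"],
                            size=spec.n_families, p=np.array(spec.structure_mix))
    model_names = list(spec.planted_model_mix)
    model_draws = rng.choice(model_names, size=spec.n_families,
                             p=np.array([spec.planted_model_mix[m] for m in model_names]))
    ern_draws = rng.choice(ERNS, size=spec.n_families, p=np.array(ERN_WEIGHTS))
    families: list[SimFamily] = []
    for i in range(spec.n_families):
        model = str(model_draws[i])
        sex = "male" if (model == "XL" or rng.random() < spec.male_fraction) else "female"
        families.append(SimFamily(
            family_id=f"FAM{i + 1:04d}", structure=str(structures[i]),
            model=model, ern=str(ern_draws[i]), index_sex=sex))

    # --- background site pool ----------------------------------------------
    n_x = max(1, int(spec.n_background_sites * 0.06))
    n_mt = max(1, int(spec.n_background_sites * 0.02))
    n_auto = spec.n_background_sites - n_x - n_mt
    used_positions: dict[str, set[int]] = {c: set() for c in GENOME}
    sites: list[SimSite] = []

    def _place_site(contig_genes: list[SimGene]) -> tuple[SimGene, int]:
        while True:
            g = contig_genes[rng.integers(len(contig_genes))]
            pos = int(rng.integers(g.start, g.end + 1))
            if pos not in used_positions[g.contig]:
                used_positions[g.contig].add(pos)
                return g, pos

    auto_genes = [g for g in genes if g.contig in AUTOSOMES]
    x_genes = [g for g in genes if g.contig == "X"]
    mt_genes = [g for g in genes if g.contig == "MT"]
    for pool, count in ((auto_genes, n_auto), (x_genes, n_x), (mt_genes, n_mt)):
        for _ in range(count):
            g, pos = _place_site(pool)
            ref, alt = _snv(rng)
            sites.append(SimSite(
                contig=g.contig, pos=pos, ref=ref, alt=alt, gene=g.symbol,
                consequence=str(rng.choice(_CONSEQUENCES, p=np.array(_CONSEQ_W))),
                af=_log_uniform(rng, *spec.background_af_range)))

    # --- planted variants ---------------------------------------------------
    truth_rows: list[dict] = []
    roh_windows: dict[str, tuple[str, int, int]] = {}  # family -> (contig, lo, hi)

    def _plant(fam: SimFamily, gene: SimGene,
               genotypes: dict[str, tuple[str, Optional[float]]],
               detectable: bool, status: str, note: str = "",
               af: Optional[float] = None) -> SimSite:
        while True:
            pos = int(rng.integers(gene.start, gene.end + 1))
            if pos not in used_positions[gene.contig]:
                used_positions[gene.contig].add(pos)
                break
        ref, alt = _snv(rng)
        site = SimSite(
            contig=gene.contig, pos=pos, ref=ref, alt=alt, gene=gene.symbol,
            consequence=str(rng.choice(_CONSEQUENCES[:4])),
            af=af if af is not None else _log_uniform(rng, *spec.planted_af_range),
            planted_by=fam.family_id, planted_genotypes=genotypes)
        sites.append(site)
        truth_rows.append({
            "family_id": fam.family_id, "index_id": fam.index_id, "ern": fam.ern,
            "model": fam.model, "contig": site.contig, "pos": site.pos,
            "ref": site.ref, "alt": site.alt, "gene": gene.symbol,
            "expected_detectable": detectable, "expected_status": status,
            "note": note,
        })
        return site

    for fam in families:
        mode = _required_mode(fam.model)
        idx, fa, mo = fam.index_id, fam.father_id, fam.mother_id
        if fam.model == "none":
            if rng.random() < spec.decoy_rate:
                pool = [genes_by_symbol[s] for s in panels[fam.ern]
                        if genes_by_symbol[s].mode == "AD"]
                gene = pool[rng.integers(len(pool))]
                gts = {idx: ("0/1", None)}
                if fa:
                    gts[fa] = ("0/1", None)
                if mo:
                    gts[mo] = ("0/0", None)
                _plant(fam, gene, gts, detectable=False, status="none",
                       note="decoy: common allele, fails rarity filter",
                       af=spec.decoy_af)
            continue

        pool = [genes_by_symbol[s] for s in panels[fam.ern]
                if genes_by_symbol[s].mode == mode]
        gene = pool[rng.integers(len(pool))]

        if fam.model in ("AD-denovo", "mosaic"):
            frac = float(rng.uniform(0.05, 0.25)) if fam.model == "mosaic" else None
            gts = {idx: ("0/1", frac)}
            if fa:
                gts[fa] = ("0/0", None)
            if mo:
                gts[mo] = ("0/0", None)
            _plant(fam, gene, gts, True, "candidate")
        elif fam.model == "AD-inherited":
            gts = {idx: ("0/1", None)}
            if mo:
                gts[mo] = ("0/1", None)  # transmitting parent, affected in PED
            if fa:
                gts[fa] = ("0/0", None)
            _plant(fam, gene, gts, True, "candidate")
        elif fam.model in ("AR-hom", "AR-hom-in-ROH"):
            gts = {idx: ("1/1", None)}
            if fa:
                gts[fa] = ("0/1", None)
            if mo:
                gts[mo] = ("0/1", None)
            site = _plant(fam, gene, gts, True, "candidate")
            if fam.model == "AR-hom-in-ROH":
                roh_windows[fam.family_id] = (
                    site.contig,
                    max(1, site.pos - spec.roh_flank_bp),
                    min(GENOME[site.contig], site.pos + spec.roh_flank_bp))
        elif fam.model == "AR-comphet":
            gts1 = {idx: ("0/1", None)}
            gts2 = {idx: ("0/1", None)}
            if fa:
                gts1[fa] = ("0/1", None)
                gts2[fa] = ("0/0", None)
            if mo:
                gts1[mo] = ("0/0", None)
                gts2[mo] = ("0/1", None)
            _plant(fam, gene, gts1, True, "candidate", note="comphet paternal")
            _plant(fam, gene, gts2, True, "candidate", note="comphet maternal")
        elif fam.model == "XL":
            gts = {idx: ("1", None)}  # hemizygous male index
            if mo:
                gts[mo] = ("0/1", None)
            if fa:
                gts[fa] = ("0", None)
            _plant(fam, gene, gts, True, "candidate")
        elif fam.model == "MT":
            gts = {m: ("1", 0.9 if m == idx else None) for m in ([idx] + ([mo] if mo else []))}
            if fa:
                gts[fa] = ("0", None)
            _plant(fam, gene, gts, True, "candidate")
        elif fam.model == "het-AR-only":
            gts = {idx: ("0/1", None)}
            if mo:
                gts[mo] = ("0/1", None)
            if fa:
                gts[fa] = ("0/0", None)
            _plant(fam, gene, gts, True, "het_AR_candidate",
                   note="single het in recessive gene")

    sites.sort(key=lambda s: (list(GENOME).index(s.contig), s.pos))

    # --- per-family genotype draws and VCFs ---------------------------------
    for fam in families:
        _write_family_vcf(fam, sites, roh_windows.get(fam.family_id), spec, rng,
                          out / "vcfs" / f"{fam.family_id}.vcf")

    # --- PED ----------------------------------------------------------------
    ped_lines = []
    for fam in families:
        sex_code = {"male": "1", "female": "2"}[fam.index_sex]
        fa, mo = fam.father_id or "0", fam.mother_id or "0"
        if fam.structure == "singleton":
            fa = mo = "0"
        ped_lines.append(f"{fam.family_id}\t{fam.index_id}\t{fa}\t{mo}\t{sex_code}\t2")
        if fam.father_id:
            ped_lines.append(f"{fam.family_id}\t{fam.father_id}\t0\t0\t1\t1")
        if fam.mother_id:
            # the transmitting mother of an AD-inherited family is affected
            aff = "2" if fam.model == "AD-inherited" else "1"
            ped_lines.append(f"{fam.family_id}\t{fam.mother_id}\t0\t0\t2\t{aff}")
    (out / "cohort.ped").write_text("\n".join(ped_lines) + "\n")

    # --- phenotypes ---------------------------------------------------------
    planted_gene_of = {r["family_id"]: r["gene"] for r in truth_rows
                      if r["expected_detectable"]}
    pheno = []
    for fam in families:
        gene = planted_gene_of.get(fam.family_id)
        terms = list(gene_terms.get(gene, []))
        terms.append(leaves[int(rng.integers(len(leaves)))])
        pheno.append({
            "subject": {"id": fam.index_id, "sex": fam.index_sex.upper()},
            "phenotypicFeatures": [{"type": {"id": t, "label": f"synthetic term {t}"}}
                                   for t in sorted(set(terms))],
            "diseases": [{"term": {"id": f"ORPHA:{900000 + int(rng.integers(999))}"}}],
            "ern": fam.ern,
            "consanguinity": True if fam.model == "AR-hom-in-ROH" else False,
        })
    (out / "phenotypes.json").write_text(json.dumps(pheno, indent=1) + "\n")

    # --- knowledge tables ---------------------------------------------------
    _write_knowledge(spec, rng, sites, genes, gene_terms, out / "knowledge")
    _write_obo(ont_parents, out / "ontology" / "hp.obo")
    for ern, syms in panels.items():
        (out / "panels" / f"{ern}.tsv").write_text(
            "gene\n" + "\n".join(syms) + "\n")

    # --- CNV file: random het deletions + one over an AR-hom candidate ------
    cnv_lines = []
    planted_positions = {(r["contig"], r["pos"]) for r in truth_rows}
    ar_hom_rows = [r for r in truth_rows if r["model"] == "AR-hom"]
    if ar_hom_rows:
        r = ar_hom_rows[0]
        cnv_lines.append(f"{r['contig']}\t{r['pos'] - 5001}\t{r['pos'] + 5000}\t"
                         f"{r['index_id']}\tdeletion-het")
        for t in truth_rows:
            if t is r:
                t["note"] = (t["note"] + ";" if t["note"] else "") + "cnv_overlap"
    for _ in range(10):
        fam = families[int(rng.integers(len(families)))]
        contig = AUTOSOMES[int(rng.integers(2))]
        while True:
            start = int(rng.integers(1, GENOME[contig] - 20_000))
            if not any(c == contig and start <= p <= start + 10_000
                       for c, p in planted_positions):
                break
        cnv_lines.append(f"{contig}\t{start}\t{start + 10_000}\t{fam.index_id}\tdeletion-het")
    (out / "cnv" / "cnv.bed").write_text("\n".join(cnv_lines) + "\n")

    # --- truth + family tables ----------------------------------------------
    truth = pd.DataFrame(truth_rows)
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    fam_frame = pd.DataFrame([{
        "family_id": f.family_id, "index_id": f.index_id, "structure": f.structure,
        "model": f.model, "ern": f.ern, "index_sex": f.index_sex} for f in families])
    fam_frame.to_csv(out / "families.tsv", sep="\t", index=False)

    # --- run configuration ---------------------------------------------------
    config_path = out / "config.yaml"
    config_path.write_text(
        "preset: low_hanging_fruit\n"
        "inputs:\n"
        "  vcf_dir: vcfs\n"
        "  ped: cohort.ped\n"
        "  phenotypes: phenotypes.json\n"
        "  knowledge:\n"
        "    assertions: knowledge/assertions.tsv\n"
        "    frequencies: knowledge/frequencies.tsv\n"
        "    gene2disease: knowledge/gene2disease.tsv\n"
        "    constraint: knowledge/constraint.tsv\n"
        "    acmg: knowledge/acmg.tsv\n"
        "  panels_dir: panels\n"
        "  ontology: ontology/hp.obo\n"
        "  hpo_gene_map: knowledge/hpo2gene.tsv\n"
        "  cnv: cnv/cnv.bed\n"
        "registry: registry.json\n"
        "output_dir: out\n"
        f"autosome_length: {AUTOSOME_LENGTH}\n"
        "filters:\n"
        "  af_external_max: 0.01\n"
        "  af_internal_max: 0.02\n"
        "  require_plp: true\n"
        "roh:\n"
        "  min_length_bp: 1000000\n"
        "  min_sites: 25\n"
        "  max_het: 1\n"
        "froh:\n"
        "  threshold: 0.03\n"
        "mosaic:\n"
        "  af_bound: 0.30\n")
    return SimResult(out_dir=out, truth=truth, families=fam_frame,
                     config_path=config_path)


# ---------------------------------------------------------------------------
# VCF construction
# ---------------------------------------------------------------------------

def _transmit(rng: np.random.Generator, parent_count: Optional[int], af: float) -> int:
    """One allele from a parent (HWE draw when the parent is absent)."""
    if parent_count is None:
        return int(rng.random() < af)
    return int(rng.random() < parent_count / 2)


def _ad_string(rng: np.random.Generator, gt: str, frac: Optional[float]) -> str:
    dp = 50
    if gt in (".", "./."):
        return "."
    if frac is not None:
        alt = max(1, round(100 * frac))
        return f"{100 - alt},{alt}"
    n_alt = gt.count("1")
    ploidy = 1 if "/" not in gt else 2
    if n_alt == 0:
        return f"{dp},0"
    if n_alt == ploidy:
        return f"0,{dp}"
    alt = int(np.clip(rng.binomial(dp, 0.5), 15, 35))
    return f"{dp - alt},{alt}"


def _write_family_vcf(fam: SimFamily, sites: list[SimSite],
                      roh_window: Optional[tuple[str, int, int]],
                      spec: SimSpec, rng: np.random.Generator, path: Path) -> None:
    members = fam.member_ids
    idx, fa, mo = fam.index_id, fam.father_id, fam.mother_id
    header = ["##fileformat=VCFv4.2"]
    for contig, length in GENOME.items():
        header.append(f"##contig=<ID={contig},length={length}>")
    header += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=CSQ,Number=1,Type=String,Description="Functional consequence">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(members),
    ]
    lines = header
    for site in sites:
        gts = _family_genotypes(fam, site, roh_window, spec, rng)
        cells = []
        for m in members:
            gt, frac = gts[m]
            cells.append(f"{gt}:{_ad_string(rng, gt, frac)}")
        lines.append(
            f"{site.contig}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t60\tPASS\t"
            f"GENE={site.gene};CSQ={site.consequence}\tGT:AD\t" + "\t".join(cells))
    path.write_text("\n".join(lines) + "\n")


def _family_genotypes(fam: SimFamily, site: SimSite,
                      roh_window: Optional[tuple[str, int, int]],
                      spec: SimSpec, rng: np.random.Generator,
                      ) -> dict[str, tuple[str, Optional[float]]]:
    idx, fa, mo = fam.index_id, fam.father_id, fam.mother_id
    members = fam.member_ids

    if site.planted_by is not None:
        if site.planted_by == fam.family_id:
            return {m: site.planted_genotypes.get(m, ("0/0", None)) for m in members}
        # someone else's causative variant: reference in this family
        ploidy1 = site.contig == "MT" or (site.contig == "X" and fam.index_sex == "male")
        out = {}
        for m in members:
            hap = site.contig == "MT" or (
                site.contig == "X" and (m == fa or (m == idx and fam.index_sex == "male")))
            out[m] = ("0" if hap else "0/0", None)
        return out

    af = site.af
    out: dict[str, tuple[str, Optional[float]]] = {}

    def diploid_draw() -> int:
        return int(rng.random() < af) + int(rng.random() < af)

    if site.contig == "MT":
        mo_allele = int(rng.random() < af) if mo else None
        for m in members:
            if m == mo:
                allele = mo_allele
            elif m == idx:
                allele = mo_allele if mo_allele is not None else int(rng.random() < af)
            else:
                allele = int(rng.random() < af)
            out[m] = (str(allele), None)
    elif site.contig == "X":
        mo_count = diploid_draw() if mo else None
        fa_allele = int(rng.random() < af) if fa else None
        for m in members:
            if m == mo:
                out[m] = ({0: "0/0", 1: "0/1", 2: "1/1"}[mo_count], None)
            elif m == fa:
                out[m] = (str(fa_allele), None)
            elif fam.index_sex == "male":
                out[m] = (str(_transmit(rng, mo_count, af)), None)
            else:
                a = _transmit(rng, mo_count, af)
                b = fa_allele if fa_allele is not None else int(rng.random() < af)
                out[m] = ({0: "0/0", 1: "0/1", 2: "1/1"}[a + b], None)
    else:
        fa_count = diploid_draw() if fa else None
        mo_count = diploid_draw() if mo else None
        child = _transmit(rng, fa_count, af) + _transmit(rng, mo_count, af)
        counts = {idx: child}
        if fa:
            counts[fa] = fa_count
        if mo:
            counts[mo] = mo_count
        if roh_window and site.contig == roh_window[0] \
                and roh_window[1] <= site.pos <= roh_window[2]:
            counts[idx] = 0  # autozygous stretch: force the index homozygous
            for parent in (fa, mo):
                if parent and counts[parent] == 2:
                    counts[parent] = 1  # keep transmission Mendelian
        for m in members:
            out[m] = ({0: "0/0", 1: "0/1", 2: "1/1"}[counts[m]], None)

    # sprinkle missing calls over background sites only
    for m in members:
        if rng.random() < spec.missing_rate:
            ploidy1 = len(out[m][0]) == 1
            out[m] = ("." if ploidy1 else "./.", None)
    return out


# ---------------------------------------------------------------------------
# knowledge tables
# ---------------------------------------------------------------------------

def _write_knowledge(spec: SimSpec, rng: np.random.Generator, sites: list[SimSite],
                     genes: list[SimGene], gene_terms: dict[str, list[str]],
                     kdir: Path) -> None:
    planted = [s for s in sites if s.planted_by is not None]
    background = [s for s in sites if s.planted_by is None]

    assertion_rows = []
    acmg_rows = []
    for s in planted:
        decoy = s.af >= 0.01
        sig = "pathogenic" if rng.random() < 0.7 else "likely_pathogenic"
        year = _draw_year(rng, spec.variant_year_weights)
        assertion_rows.append((s, sig, f"synthetic disorder linked to {s.gene}", year))
        acmg_rows.append((s, sig, "PVS1,PM2" if sig == "pathogenic" else "PM2,PP3"))
    bg_sample_idx = rng.choice(len(background), size=min(120, len(background)),
                               replace=False)
    for i in sorted(bg_sample_idx):
        s = background[int(i)]
        if rng.random() < spec.background_plp_rate:
            sig = "pathogenic"
            assertion_rows.append((s, sig, f"synthetic disorder linked to {s.gene}",
                                   _draw_year(rng, spec.variant_year_weights)))
        else:
            sig = str(rng.choice(["benign", "likely_benign", "vus"]))
            assertion_rows.append((s, sig, "", None))
            if rng.random() < 0.1:  # a second, discordant submission
                assertion_rows.append((s, "vus" if sig != "vus" else "likely_benign",
                                       "", None))
        acmg_rows.append((s, "vus" if sig == "vus" else "likely_benign", ""))

    lines = ["## version=sim-assertions-2020-01-13",
             "contig\tpos\tref\talt\tsignificance\tcondition\tfirst_plp_year"]
    for s, sig, cond, year in assertion_rows:
        lines.append(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{sig}\t{cond}\t"
                     f"{year if year is not None else ''}")
    (kdir / "assertions.tsv").write_text("\n".join(lines) + "\n")

    lines = ["## version=sim-frequencies-2020-01",
             "contig\tpos\tref\talt\taf"]
    for s in sites:
        if s.planted_by is not None and s.af < 0.01 and rng.random() < 0.3:
            continue  # a third of rare causative variants are absent from the catalogue
        lines.append(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.af:.6g}")
    (kdir / "frequencies.tsv").write_text("\n".join(lines) + "\n")

    lines = ["## version=sim-gene2disease-2020",
             "gene\tomim_id\tinheritance\tfirst_year"]
    for i, g in enumerate(g for g in genes if g.mode):
        year = _draw_year(rng, spec.gene_year_weights)
        lines.append(f"{g.symbol}\tOMIM:{600000 + i}\t{g.mode}\t{year}")
    (kdir / "gene2disease.tsv").write_text("\n".join(lines) + "\n")

    lines = ["## version=sim-constraint-gnomad-2.1.1", "gene\tpli\toe"]
    for g in genes:
        if g.mode:
            pli, oe = rng.uniform(0.9, 1.0), rng.uniform(0.02, 0.35)
        else:
            pli, oe = rng.uniform(0.0, 1.0), rng.uniform(0.2, 1.5)
        lines.append(f"{g.symbol}\t{pli:.4f}\t{oe:.4f}")
    (kdir / "constraint.tsv").write_text("\n".join(lines) + "\n")

    lines = ["## version=sim-intervar-2020", "contig\tpos\tref\talt\tclass\tcriteria"]
    for s, cls, criteria in acmg_rows:
        lines.append(f"{s.contig}\t{s.pos}\t{s.ref}\t{s.alt}\t{cls}\t{criteria}")
    (kdir / "acmg.tsv").write_text("\n".join(lines) + "\n")

    lines = ["hpo_id\tgene"]
    for symbol in sorted(gene_terms):
        for term in gene_terms[symbol]:
            lines.append(f"{term}\t{symbol}")
    (kdir / "hpo2gene.tsv").write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# first-cousin offspring simulation (FROH calibration)
# ---------------------------------------------------------------------------

def simulate_first_cousin_offspring(
    seed: int, n_chrom: int = 30, chrom_length_bp: int = 100_000_000,
    site_spacing_bp: int = 250_000, maf: float = 0.3, cm_per_mb: float = 1.0,
) -> tuple[list[tuple[str, int, int]], float, int]:
    """Gene-drop an offspring of first cousins and genotype it.

    Founder haplotypes are labelled and dropped through the six meioses of the
    first-cousin loop with Poisson recombination (expected inbreeding
    coefficient F = 1/16). Returns (called genotype sites for
    :func:`varprio.inheritance.detect_roh`, the realized autozygous fraction,
    the simulated autosome length). Sites are biallelic with the given minor
    allele frequency, so non-autozygous tracts are heterozygous often enough
    to delimit runs of homozygosity.
    """
    rng = np.random.default_rng(seed)
    n_sites = chrom_length_bp // site_spacing_bp
    positions = (np.arange(n_sites) + 1) * site_spacing_bp
    morgans = chrom_length_bp / 1e6 * cm_per_mb / 100.0

    def meiosis(h1: np.ndarray, h2: np.ndarray) -> np.ndarray:
        n_x = rng.poisson(morgans)
        xs = np.sort(rng.uniform(0, chrom_length_bp, n_x))
        phase = (np.searchsorted(xs, positions) + rng.integers(0, 2)) % 2
        return np.where(phase == 0, h1, h2)

    sites: list[tuple[str, int, int]] = []
    autozygous_total = 0
    for c in range(n_chrom):
        founders = [np.full(n_sites, l) for l in range(8)]  # A,B share grandparents
        s1 = (meiosis(founders[0], founders[1]), meiosis(founders[2], founders[3]))
        s2 = (meiosis(founders[0], founders[1]), meiosis(founders[2], founders[3]))
        p1 = (meiosis(*s1), founders[4])
        p2 = (meiosis(*s2), founders[6])
        child = (meiosis(*p1), meiosis(*p2))
        auto = child[0] == child[1]
        autozygous_total += int(auto.sum())
        founder_alleles = (rng.random((8, n_sites)) < maf).astype(int)
        g = founder_alleles[child[0], np.arange(n_sites)] \
            + founder_alleles[child[1], np.arange(n_sites)]
        contig = str(c + 1)
        for p, count in zip(positions, g):
            sites.append((contig, int(p), int(count)))
    true_froh = autozygous_total / (n_chrom * n_sites)
    return sites, true_froh, n_chrom * chrom_length_bp
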