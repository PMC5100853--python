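"""End-to-end orchestration of the analysis stages.

preprocess -> align/annotate -> isomiR classification -> quantification /
differential expression -> profile clustering -> (optional) overlap stats.
Every stage writes diff-able TSVs carrying a provenance header (package
version, config hash, seed), and classification work is cached per unique
read sequence across libraries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path
import pandas as pd

from . import __version__, align, isomir, overlap, preprocess, profiles, quantify
from .reference import ReferenceBundle
from .synthetic import GENOTYPES, TIMEPOINTS

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    reference_dir: str
    manifest: str  # TSV: library_id, genotype, timepoint, replicate, fastq
    outdir: str
    adapter: str
    seed: int = 0
    q_min: int = 20
    len_min: int = 18
    len_max: int = 30
    max_mm: int = 3
    deplete: bool = True
    min_rpm: float = 1.0
    min_libraries: int = 6
    cluster_min_rpm: float = 10.0
    k: int = 5
    fdr_max: float = 0.05
    gene_universe: str | None = None  # optional: universe size or list path
    gene_list_a: str | None = None
    gene_list_b: str | None = None

    def config_hash(self) -> str:
        payload = {k: v for k, v in asdict(self).items() if k != "outdir"}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def _provenance_lines(config: PipelineConfig, stage: str, params: dict) -> list[str]:
    return [
        f"# srnapipe {__version__} stage={stage} config={config.config_hash()} seed={config.seed}",
        "# params " + " ".join(f"{k}={v}" for k, v in sorted(params.items())),
    ]


def write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig, stage: str, params: dict | None = None, index: bool = True) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(config, stage, params or {}):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=index)


def read_tsv(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=index_col)


def load_manifest(path: str | Path) -> pd.DataFrame:
    manifest = pd.read_csv(path, sep="\t", comment="#")
    required = {"library_id", "genotype", "timepoint", "replicate", "fastq"}
    missing = required - set(manifest.columns)
    if missing:
        raise ValueError(f"manifest lacks columns {sorted(missing)}")
    return manifest


def design_is_complete(manifest: pd.DataFrame) -> bool:
    for g in GENOTYPES:
        for t in TIMEPOINTS:
            n = ((manifest["genotype"] == g) & (manifest["timepoint"] == t)).sum()
            if n != 3:
                return False
    return True


class _ReadClassifier:
    """Shared per-sequence classification cache across libraries."""

    def __init__(self, bundle: ReferenceBundle, mirna_refs, max_mm: int):
        self.genome_index = align.ExactIndex(bundle.genome)
        self.annotator = align.Annotator(bundle)
        self.mirna_refs = mirna_refs
        self.max_mm = max_mm
        self._cache: dict[str, tuple] = {}

    def classify(self, sequence: str):
        """-> (hits, class annotation | None, isoform call | None, mapped: bool)"""
        hit = self._cache.get(sequence)
        if hit is not None:
            return hit
        hits = self.genome_index.query(sequence)
        if hits:
            ann = self.annotator.annotate_class(sequence, hits)
            call = (
                isomir.classify_templated(sequence, hits, self.mirna_refs)
                if ann.representative_class == "mirna"
                else None
            )
            result = (hits, ann, call, True)
        else:
            call = isomir.detect_nta(
                sequence, self.genome_index, self.mirna_refs, max_mm=self.max_mm
            )
            result = ([], None, call, call is not None)
        self._cache[sequence] = result
        return result


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; returns the key tables and writes TSVs under outdir."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_handler = logging.FileHandler(outdir / "run_log.txt")
    log_handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("srnapipe")
    root.addHandler(log_handler)
    root.setLevel(logging.INFO)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(log_handler)


def _run(config: PipelineConfig, outdir: Path) -> dict:
    logger.info("pipeline start: config=%s params=%s", config.config_hash(), asdict(config))
    refdir = Path(config.reference_dir)
    if not refdir.exists():
        raise FileNotFoundError(f"stage=reference: missing {refdir}")
    bundle = ReferenceBundle.from_dir(refdir)
    mirna_refs = isomir.build_mirna_refs(
        refdir / "mirna.gff3", refdir / "hairpin.fa", refdir / "mature.fa"
    )
    manifest = load_manifest(config.manifest)
    blocklist: list[str] = []
    if config.deplete and (refdir / "blocklist.fa").exists():
        blocklist = preprocess.load_blocklist(refdir / "blocklist.fa")

    classifier = _ReadClassifier(bundle, mirna_refs, config.max_mm)
    mirna_ids = [ann.mirna_id for ann in mirna_refs]
    iso_counts = {k: {} for k in isomir.ISOFORM_KINDS}
    library_sizes = {}
    composition_frames = []
    stats_rows = []

    for rec in manifest.itertuples():
        lib = rec.library_id
        fastq = Path(rec.fastq)
        if not fastq.exists():
            raise FileNotFoundError(f"stage=preprocess: missing FASTQ {fastq}")
        reads, stats = preprocess.process_fastq(
            fastq, config.adapter, q_min=config.q_min,
            len_min=config.len_min, len_max=config.len_max, library_id=lib,
        )
        if blocklist:
            reads = preprocess.deplete_sequences(reads, blocklist, stats)
        (outdir / "preprocess").mkdir(parents=True, exist_ok=True)
        preprocess.write_collapsed_fasta(reads, outdir / "preprocess" / f"{lib}.collapsed.fa")
        stats_rows.append({"library_id": lib, **stats.as_dict()})

        annotations, ann_counts, calls, call_counts = [], [], [], []
        mapped_total = 0.0
        for read in reads:
            hits, ann, call, mapped = classifier.classify(read.sequence)
            if not mapped:
                continue
            mapped_total += read.count
            if ann is not None:
                annotations.append(ann)
                ann_counts.append(read.count)
            if call is not None and call.isoform in isomir.ISOFORM_KINDS:
                calls.append(call)
                call_counts.append(read.count)
            elif call is None and ann is None:
                continue
        if annotations:
            comp = align.class_composition(annotations, ann_counts)
            comp.insert(0, "library_id", lib)
            composition_frames.append(comp)
        library_sizes[lib] = mapped_total
        iso_table = isomir.quantify_isoforms(calls, call_counts, mirna_ids)
        for kind in isomir.ISOFORM_KINDS:
            iso_counts[kind][lib] = iso_table[kind]
        logger.info("library %s: %d collapsed reads, %.0f mapped", lib, len(reads), mapped_total)

    stats_df = pd.DataFrame(stats_rows).set_index("library_id")
    write_tsv(stats_df, outdir / "preprocess" / "stats.tsv", config, "preprocess",
              {"adapter": config.adapter, "q_min": config.q_min,
               "len_min": config.len_min, "len_max": config.len_max})
    composition = pd.concat(composition_frames, ignore_index=True)
    write_tsv(composition, outdir / "annotate" / "composition.tsv", config, "annotate", {}, index=False)

    sizes = pd.Series(library_sizes, name="library_size")
    counts = {k: pd.DataFrame(v) for k, v in iso_counts.items()}
    design = manifest.set_index("library_id")[["genotype", "timepoint", "replicate"]]
    for kind, df in counts.items():
        write_tsv(df, outdir / "isomir" / f"counts_{kind}.tsv", config, "isomir", {})
    write_tsv(sizes.to_frame(), outdir / "isomir" / "library_sizes.tsv", config, "isomir", {})

    results: dict = {
        "composition": composition,
        "counts": counts,
        "library_sizes": sizes,
        "design": design,
        "stats": stats_df,
    }

    rpms = {k: quantify.rpm(df, sizes) for k, df in counts.items()}
    results["rpm"] = rpms

    if not design_is_complete(manifest):
        logger.warning("incomplete design: skipping DE, clustering and subset stages")
        return results

    # Table-1-shaped isoform summary over expressed miRNAs
    totals_all = sum(rpms.values())
    expressed = totals_all.index[
        profiles.sample_set_means(totals_all, design).ge(10.0).any(axis=1)
    ]
    components = pd.DataFrame(
        {
            kind: profiles.sample_set_means(rpms[kind].loc[expressed], design).sum(axis=0)
            for kind in isomir.ISOFORM_KINDS
        }
    )
    summary = isomir.isoform_summary(components)
    write_tsv(summary, outdir / "isomir" / "isoform_summary.tsv", config, "isomir", {"min_total_rpm": 10})
    results["isoform_summary"] = summary

    # TMM factors are estimated on the class/subtype composition matrix: the
    # background classes (structural, TE, introns, ...) are the stable bulk of
    # each library, whereas the miRNA matrix itself carries the genotype
    # effect and would absorb it as apparent composition bias.
    comp_matrix = composition.pivot_table(
        index=["class", "subtype"], columns="library_id", values="weighted_count", fill_value=0.0
    )[list(sizes.index)]
    tmm = quantify.tmm_factors(comp_matrix, sizes)
    tmm.name = "tmm_factor"
    write_tsv(tmm.to_frame(), outdir / "quantify" / "tmm_factors.tsv", config, "quantify", {})
    rpm_canonical = rpms["canonical"]
    keep = quantify.filter_expressed(rpm_canonical, config.min_rpm, config.min_libraries)
    logger.info("expression filter: %d of %d features kept", len(keep), len(rpm_canonical))
    de_results = {}
    if len(keep) >= 2:
        cm_filt = quantify.CountMatrix(counts["canonical"].loc[keep], design, library_sizes=sizes)
        for tp in ("F0_2h", "F2_4h"):
            de = quantify.nb_glm_lrt(cm_filt, tp, norm_factors=tmm)
            de_results[tp] = de
            write_tsv(de, outdir / "quantify" / f"de_mut_vs_wt_{tp}.tsv", config, "quantify",
                      {"contrast": f"mut_vs_wt@{tp}", "fdr_max": config.fdr_max})
    results["tmm"] = tmm
    results["de"] = de_results

    canonical_sets = profiles.sample_set_means(rpm_canonical, design)
    clusterable = profiles.select_canonical_for_clustering(canonical_sets, config.cluster_min_rpm)
    if len(clusterable) >= config.k:
        assignment = profiles.cluster_classes(canonical_sets.loc[clusterable], k=config.k)
        summary_classes = profiles.class_summary(assignment, canonical_sets.loc[clusterable])
        write_tsv(assignment.labels.to_frame(), outdir / "profiles" / "classes.tsv", config,
                  "profiles", {"k": config.k, "min_rpm": config.cluster_min_rpm})
        write_tsv(summary_classes, outdir / "profiles" / "class_summary.tsv", config, "profiles", {})
        results["classes"] = assignment
        results["class_summary"] = summary_classes
    else:
        logger.warning("too few clusterable miRNAs (%d); skipping clustering", len(clusterable))

    iso_sets = {k: profiles.sample_set_means(v, design) for k, v in rpms.items()}
    nonc = profiles.select_noncanonical_subset(
        iso_sets["canonical"], iso_sets["noncanonical"], iso_sets["nta"]
    )
    nta_sel = profiles.select_nta_subset(
        iso_sets["canonical"], iso_sets["noncanonical"], iso_sets["nta"]
    )
    write_tsv(nonc, outdir / "profiles" / "subset_noncanonical.tsv", config, "profiles", {})
    write_tsv(nta_sel, outdir / "profiles" / "subset_nta.tsv", config, "profiles", {})
    results["subset_noncanonical"] = nonc
    results["subset_nta"] = nta_sel

    if de_results:
        down = profiles.select_downregulated_mirnas(
            de_results, canonical_sets, fdr_max=config.fdr_max, min_rpm=config.cluster_min_rpm
        )
        pd.Series(down, name="mirna_id").to_csv(
            outdir / "profiles" / "downregulated.tsv", sep="\t", index=False
        )
        results["downregulated"] = down

    if config.gene_list_a and config.gene_list_b and config.gene_universe:
        list_a = overlap.read_gene_list(config.gene_list_a)
        list_b = overlap.read_gene_list(config.gene_list_b)
        universe = int(config.gene_universe)
        report = overlap.overlap_report([("listA_vs_listB", universe, list_a, list_b)])
        write_tsv(report, outdir / "overlap" / "report.tsv", config, "overlap", {}, index=False)
        results["overlap"] = report

    logger.info("pipeline complete")
    return results
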