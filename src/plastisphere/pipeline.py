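"""Run the whole analysis from one configuration.

A run configuration is a nested mapping (usually loaded from YAML) with a
master ``seed``, an output directory, the list of enabled ``stages`` and a
``parameters`` section whose defaults are the experiment's standard values:
minimum sample depth 1000 reads, coloniser inclusion threshold 0.5%,
HMM E-value cutoffs 0.01 and 1e-4, identity thresholds 90/95/97/99%,
5-degree grid cells and alpha = 0.05.

Stages run in dependency order (ecology, succession and curve analysis need
counts; trait prediction needs counts plus the reference collection).  Every
stage writes TSV outputs into the run directory, and a JSON manifest
records each stage's parameters and the SHA-256 of every file written:
rerunning an identical configuration reproduces identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field

import pandas as pd
import yaml

from . import ecology, prc, screens, spectra, succession, synthetic, traits
from .containers import CountMatrix
from .hmm import build_profile, calibrate_and_search
from .io import ensure_dir, read_counts, write_counts, write_fasta, write_table
from .ordination import nmds

logger = logging.getLogger(__name__)

STAGE_ORDER = ("simulate", "ecology", "prc", "succession", "traits",
               "ftir", "screens")

DEFAULT_PARAMETERS: dict = {
    "min_reads": 1000,
    "min_abund": 0.005,
    "e_cutoffs": [0.01, 1e-4],
    "identity_thresholds": [90.0, 95.0, 97.0, 99.0],
    "cell_size": 5.0,
    "alpha": 0.05,
    "n_permutations": 999,
    "log_offset": 1.0,
    "min_sum_log_abundance": 100.0,
    "prc_upper": 2.0,
    "prc_lower": 0.9,
    "control": "no carbon control",
    "custom_family": "PETase",
    "nmds_starts": 4,
}


@dataclass
class RunConfig:
    seed: int = 0
    outdir: str = "plastisphere_run"
    stages: tuple[str, ...] = ("simulate", "ecology", "prc", "succession",
                               "traits", "ftir", "screens")
    parameters: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        params = dict(DEFAULT_PARAMETERS)
        params.update(self.parameters)
        self.parameters = params
        for key, path in self.inputs.items():
            if not os.path.exists(path):
                raise FileNotFoundError(f"input {key!r}: {path} does not exist")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            seed=int(raw.get("seed", 0)),
            outdir=raw.get("outdir", "plastisphere_run"),
            stages=tuple(raw.get("stages", cls.stages)),
            parameters=raw.get("parameters", {}),
            inputs=raw.get("inputs", {}),
        )


def init_config() -> str:
    """A YAML template with all defaults spelled out."""
    template = {
        "seed": 0,
        "outdir": "plastisphere_run",
        "stages": list(STAGE_ORDER),
        "parameters": dict(DEFAULT_PARAMETERS),
        "inputs": {},
    }
    return yaml.safe_dump(template, sort_keys=False)


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class _Run:
    def __init__(self, config: RunConfig):
        self.config = config
        self.outdir = ensure_dir(config.outdir)
        self.manifest: list[dict] = []
        self.counts: CountMatrix | None = None
        self.truth: pd.DataFrame | None = None
        self.reference: dict | None = None
        self.spectra: dict | None = None
        self.intensities = None

    def record(self, stage: str, params: dict, paths: list[str]) -> None:
        self.manifest.append({
            "stage": stage,
            "parameters": params,
            "outputs": {os.path.relpath(p, self.outdir): _sha256(p)
                        for p in sorted(paths)},
        })

    def path(self, name: str) -> str:
        return os.path.join(self.outdir, name)

    # -- stage implementations ------------------------------------------

    def stage_simulate(self) -> None:
        cfg = self.config
        scn = synthetic.default_succession_scenario(seed=cfg.seed)
        self.counts, self.truth = synthetic.generate_community_series(scn)
        self.reference = synthetic.generate_reference_collection(
            synthetic.ReferenceScenario(seed=cfg.seed)
        )
        self.spectra_scn = synthetic.SpectrumScenario(seed=cfg.seed)
        self.spectra, self.spectra_truth = synthetic.generate_spectra(self.spectra_scn)
        fcs = [1.0] * 197 + [2.1, 3.5, 2.3]
        self.intensities, self.intensity_labels, self.intensity_truth = (
            synthetic.generate_intensity_table(fcs, seed=cfg.seed)
        )

        paths = [self.path(n) for n in
                 ("counts.tsv", "metadata.tsv", "community_truth.tsv",
                  "reference_16s.fasta", "asv_queries.fasta", "traits.tsv",
                  "seed_alignment.fasta", "reference_truth.tsv",
                  "spectra_truth.tsv", "intensities.tsv", "intensity_truth.tsv")]
        write_counts(self.counts, paths[0], paths[1])
        write_table(self.truth, paths[2])
        write_fasta(self.reference["reference_16s"], paths[3])
        write_fasta(self.reference["asv_seqs"], paths[4])
        write_table(self.reference["traits"], paths[5])
        write_fasta(self.reference["seed_alignment"], paths[6])
        write_table(self.reference["truth"], paths[7])
        write_table(self.spectra_truth, paths[8])
        write_table(self.intensities, paths[9])
        write_table(self.intensity_truth, paths[10])
        proteome_dir = ensure_dir(self.path("proteomes"))
        for genome, prots in self.reference["proteomes"].items():
            p = os.path.join(proteome_dir, f"{genome}.faa")
            write_fasta(prots, p)
            paths.append(p)
        self.record("simulate", {"seed": cfg.seed}, paths)

    def _require_counts(self, stage: str) -> CountMatrix:
        if self.counts is None:
            inputs = self.config.inputs
            if "counts" in inputs and "metadata" in inputs:
                self.counts = read_counts(inputs["counts"], inputs["metadata"])
            else:
                raise ValueError(
                    f"stage {stage!r} needs counts: enable 'simulate' or "
                    "provide inputs.counts and inputs.metadata"
                )
        return self.counts

    def stage_ecology(self) -> None:
        p = self.config.parameters
        cm = ecology.filter_low_depth(self._require_counts("ecology"),
                                      p["min_reads"])
        rel = cm.relative_abundance()
        dm = ecology.bray_curtis(rel)
        ordn = nmds(dm, k=2, n_starts=p["nmds_starts"], seed=self.config.seed)
        groups = cm.metadata["treatment"]
        ano = ecology.anosim(dm, groups, p["n_permutations"], seed=self.config.seed)
        per = ecology.permanova(dm, groups, p["n_permutations"], seed=self.config.seed)
        div = ecology.diversity_metrics(rel)

        paths = [self.path(n) for n in
                 ("bray_curtis.tsv", "nmds_coordinates.tsv",
                  "permutation_tests.tsv", "diversity.tsv")]
        write_table(pd.DataFrame(dm.data, index=list(dm.ids),
                                 columns=list(dm.ids)), paths[0])
        write_table(ordn.coordinates, paths[1])
        write_table(pd.DataFrame([
            {"method": r.method, "statistic": r.statistic, "p_value": r.p_value,
             "n_permutations": r.n_permutations, "stress": ordn.stress}
            for r in (ano, per)
        ]).set_index("method"), paths[2])
        write_table(div, paths[3])
        self.record("ecology", {k: p[k] for k in
                                ("min_reads", "n_permutations", "nmds_starts")},
                    paths)

    def stage_prc(self) -> None:
        p = self.config.parameters
        cm = self._require_counts("prc")
        y = prc.log_transform(cm, p["log_offset"])
        result = prc.prc_fit(y, cm.metadata["treatment"], cm.metadata["day"],
                             p["control"], log_offset=p["log_offset"])
        drivers = prc.driver_taxa(result, y, p["min_sum_log_abundance"],
                                  p["prc_upper"], p["prc_lower"])
        paths = [self.path("prc_curves.tsv"), self.path("prc_weights.tsv")]
        write_table(result.curves, paths[0])
        write_table(drivers, paths[1])
        self.record("prc", {k: p[k] for k in
                            ("log_offset", "min_sum_log_abundance",
                             "prc_upper", "prc_lower", "control")}, paths)

    def stage_succession(self) -> None:
        p = self.config.parameters
        cm = self._require_counts("succession")
        rel = cm.relative_abundance()
        report = succession.colonisers(rel, cm.metadata, p["min_abund"])
        tables = []
        for treatment, table in sorted(report.per_treatment.items()):
            t = table.copy()
            t.insert(0, "treatment", treatment)
            tables.append(t)
        paths = [self.path("colonisers.tsv"), self.path("mean_peak_day.tsv")]
        write_table(pd.concat(tables), paths[0])
        write_table(report.mean_peak_day.to_frame(), paths[1])
        for treatment, hm in sorted(report.heatmaps.items()):
            path = self.path(
                f"heatmap_{treatment.replace(' ', '_')}.tsv")
            write_table(hm, path)
            paths.append(path)
        self.record("succession", {"min_abund": p["min_abund"]}, paths)

    def stage_traits(self) -> None:
        if self.reference is None:
            raise ValueError(
                "stage 'traits' needs the reference collection: enable "
                "'simulate' (file-based reference inputs are not wired into "
                "the orchestrator; use the library functions directly)"
            )
        p = self.config.parameters
        ref = self.reference
        profile = build_profile(ref["seed_alignment"], source="seed_alignment")
        cutoffs = sorted(p["e_cutoffs"], reverse=True)
        hits_default, counts_default = calibrate_and_search(
            profile, ref["proteomes"], e_cutoff=cutoffs[0], seed=self.config.seed
        )
        hits_strict = hits_default[hits_default["e_value"] <= cutoffs[-1]]
        counts_strict = (
            hits_strict.groupby("genome").size()
            .reindex(counts_default.index).fillna(0).astype(int)
        )
        trait_matrix = traits.TraitMatrix(
            ref["traits"].drop(columns=["planted_family_truth"])
        )
        augmented = traits.augment_traits(trait_matrix, counts_default,
                                          p["custom_family"])
        identities = traits.identity_matrix(ref["asv_seqs"], ref["reference_16s"])
        assignments = traits.assign_nearest(ref["asv_seqs"], ref["reference_16s"],
                                            identities)
        rel, _geo = synthetic.generate_geo_samples(list(ref["asv_seqs"]),
                                                   seed=self.config.seed)
        prediction = traits.predict_genes(rel, assignments, augmented)
        contrib = traits.taxon_contributions(rel, assignments, augmented)

        paths = [self.path(n) for n in
                 ("hmm_hits.tsv", "hit_counts.tsv", "augmented_traits.tsv",
                  "assignments.tsv", "gene_abundance.tsv", "weighted_nsti.tsv",
                  "contributions.tsv")]
        write_table(hits_default, paths[0], index=False)
        write_table(pd.DataFrame({"default": counts_default,
                                  "strict": counts_strict}), paths[1])
        write_table(augmented.table, paths[2])
        write_table(assignments, paths[3])
        write_table(prediction.gene_abundance, paths[4])
        write_table(prediction.weighted_nsti.to_frame(), paths[5])
        write_table(contrib, paths[6], index=False)
        self.record("traits", {"e_cutoffs": cutoffs,
                               "custom_family": p["custom_family"]}, paths)

    def stage_ftir(self) -> None:
        if self.spectra is None:
            raise ValueError("stage 'ftir' needs spectra: enable 'simulate'")
        p = self.config.parameters
        wn = self.spectra["wavenumbers"]
        indices: dict[str, list[pd.Series]] = {}
        for key, absorbance in self.spectra.items():
            if key == "wavenumbers":
                continue
            group, rep = key
            spec = spectra.preprocess(
                spectra.Spectrum(wn, absorbance, f"{group}.r{rep}", group)
            )
            indices.setdefault(group, []).append(spectra.oxidation_indices(spec))
        frames = {g: pd.DataFrame(rows) for g, rows in indices.items()}
        groups = sorted(frames)
        comparisons = []
        base = groups[0]
        for other in groups[1:]:
            comp = spectra.compare_groups(frames[base], frames[other], p["alpha"])
            comp.insert(0, "groups", f"{base} vs {other}")
            comparisons.append(comp)
        paths = [self.path("oxidation_indices.tsv"),
                 self.path("ftir_comparisons.tsv")]
        write_table(pd.concat(
            [f.assign(group=g) for g, f in sorted(frames.items())]
        ), paths[0], index=False)
        write_table(pd.concat(comparisons), paths[1])
        self.record("ftir", {"alpha": p["alpha"]}, paths)

    def stage_screens(self) -> None:
        if self.intensities is None or self.reference is None:
            raise ValueError("stage 'screens' needs simulated inputs: "
                             "enable 'simulate'")
        p = self.config.parameters
        diff = screens.differential(self.intensities, self.intensity_labels,
                                    "A", "B")
        rel, geo = synthetic.generate_geo_samples(
            list(self.reference["asv_seqs"]), seed=self.config.seed
        )
        query = next(iter(self.reference["reference_16s"].values()))
        sums = screens.match_and_sum(query, rel, self.reference["asv_seqs"],
                                     thresholds=p["identity_thresholds"])
        best_thr = sorted(p["identity_thresholds"])[-2]
        geo_table = geo.assign(summed_abundance=sums[best_thr])
        grid = screens.grid_max(geo_table, cell_size=p["cell_size"])

        paths = [self.path("proteomic_diff.tsv"),
                 self.path("biogeo_sums.tsv"), self.path("biogeo_grid.tsv")]
        write_table(diff, paths[0])
        write_table(sums, paths[1])
        write_table(grid, paths[2], index=False)
        self.record("screens",
                    {"identity_thresholds": list(p["identity_thresholds"]),
                     "cell_size": p["cell_size"]}, paths)

    # --------------------------------------------------------------------

    def run(self) -> list[dict]:
        handlers = {
            "simulate": self.stage_simulate,
            "ecology": self.stage_ecology,
            "prc": self.stage_prc,
            "succession": self.stage_succession,
            "traits": self.stage_traits,
            "ftir": self.stage_ftir,
            "screens": self.stage_screens,
        }
        enabled = [s for s in STAGE_ORDER if s in set(self.config.stages)]
        for stage in enabled:
            logger.info("running stage %s", stage)
            try:
                handlers[stage]()
            except Exception:
                self._write_manifest()  # completed stages stay on record
                raise
        self._write_manifest()
        return self.manifest

    def _write_manifest(self) -> None:
        with open(self.path("manifest.json"), "w") as fh:
            json.dump(self.manifest, fh, indent=2, sort_keys=True)


def run(config: RunConfig) -> list[dict]:
    """Execute the enabled stages; returns the manifest."""
    return _Run(config).run()
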