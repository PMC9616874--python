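"""End-to-end orchestration: simulate -> filter -> infer -> ensemble -> match -> assay.

Fully deterministic given the config seed (all stage seeds are spawned from
one ``numpy`` SeedSequence); every intermediate is written to the output
directory so any stage can be re-run from its persisted inputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import assay, ensemble, matching, network, synthetic, tables
from .config import RunConfig

__all__ = ["RunReport", "run_pipeline", "plant_pairs"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunReport:
    outdir: Path
    n_plates: int
    n_effective: int
    n_networks: int
    unique_pairs: int
    n_robust_pairs: int
    planted_recall: dict
    report_path: Path


def plant_pairs(
    source: synthetic.SourceCommunity,
    n_pairs: int,
    sign: int = 1,
    effect: float = 2.5,
    reference_dilution: int | None = None,
    target_lambda: float = 1.0,
    inoculum_volume_ul: float = 1.0,
) -> synthetic.InteractionTruth:
    """Plant pairs among species whose seeding intensity is informative.

    Dilution-to-extinction expresses an interaction as rank correlation only
    where a species' per-well founding-cell intensity lambda is near 1: much
    higher and it occupies every well (no presence contrast), much lower and
    it is too sparse to pass the prevalence filter. Given a reference
    dilution level, species are ranked by |log(lambda / target_lambda)| at
    that dilution and the closest 2*n_pairs are paired consecutively;
    without one, the most abundant species are paired instead.
    """
    if reference_dilution is None:
        order = np.argsort(source.abundances)[::-1]
    else:
        lam = source.abundances * source.cells_per_ul * inoculum_volume_ul * 10.0 ** (-reference_dilution)
        with np.errstate(divide="ignore"):
            order = np.argsort(np.abs(np.log(np.maximum(lam, 1e-300) / target_lambda)))
    pairs = []
    for k in range(n_pairs):
        a = source.species_ids[order[2 * k]]
        b = source.species_ids[order[2 * k + 1]]
        pairs.append((a, b, sign, effect))
    return synthetic.InteractionTruth(pairs=tuple(pairs))


def _spawn_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))


def simulate_array(config: RunConfig, outdir: Path | None = None):
    """Simulate every plate of the configured design; returns (plates, truths).

    ``truths`` maps sample_type -> InteractionTruth (one community with its
    planted pairs per sample type; media/dilutions/replicates share it).
    """
    sim = config.simulator
    root_ss = np.random.SeedSequence(config.seed)
    plates: list[tables.PlateTable] = []
    truths: dict[str, synthetic.InteractionTruth] = {}
    sources: dict[str, synthetic.SourceCommunity] = {}
    for sample_type in sim.sample_types:
        src_ss, plate_ss = np.random.SeedSequence(
            (config.seed, zlib.crc32(sample_type.encode()))
        ).spawn(2)
        source = synthetic.simulate_source(
            n_species=sim.n_species,
            lognormal_mu=sim.lognormal_mu,
            lognormal_sigma=sim.lognormal_sigma,
            cells_per_ul=sim.cells_per_ul,
            seed=_spawn_seed(src_ss),
        )
        truth = plant_pairs(
            source,
            sim.n_planted_pairs,
            sim.planted_sign,
            sim.planted_effect,
            reference_dilution=(
                sorted(sim.dilution_levels)[len(sim.dilution_levels) // 2]
                if sim.dilution_levels
                else None
            ),
        )
        sources[sample_type] = source
        truths[sample_type] = truth
        for medium in sim.media:
            for i, dilution in enumerate(sim.dilution_levels):
                for replicate in sim.replicates:
                    design = tables.PlateDesign(
                        sample_type=sample_type,
                        medium=medium,
                        dilution_level=dilution,
                        replicate=replicate,
                        n_wells=sim.n_wells,
                    )
                    plate, _ = synthetic.simulate_plate(
                        source,
                        truth,
                        design,
                        read_depth=sim.read_depth,
                        seed=_spawn_seed(plate_ss),
                        co_colonization=sim.co_colonization,
                    )
                    # designs may repeat a dilution level; disambiguate the id
                    if sim.dilution_levels.count(dilution) > 1:
                        plate = tables.PlateTable(
                            plate_id=f"{plate.plate_id}-{i}",
                            design=plate.design,
                            wells=plate.wells,
                            zotu_ids=plate.zotu_ids,
                            counts=plate.counts,
                        )
                    plates.append(plate)
    if outdir is not None:
        plate_dir = outdir / "plates"
        plate_dir.mkdir(parents=True, exist_ok=True)
        for plate in plates:
            tables.write_plate_table(
                plate, plate_dir / f"{plate.plate_id}.tsv", plate_dir / f"{plate.plate_id}.json"
            )
        for sample_type, truth in truths.items():
            synthetic.write_truth_pairs(truth, outdir / f"truth-{sample_type}.tsv")
    return plates, truths, sources


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunReport:
    """Run every stage; aborts with the stage name on any stage error."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    thr = config.thresholds
    stage = "simulate"
    try:
        plates, truths, sources = simulate_array(config, outdir)

        stage = "filter"
        effective = tables.effective_plates(plates, min_reads=thr.min_reads, min_grow_frac=thr.min_grow_frac)

        stage = "infer"
        networks = []
        net_dir = outdir / "networks"
        net_dir.mkdir(exist_ok=True)
        for plate in effective:
            net = network.infer_subnetwork(
                plate,
                min_reads=thr.min_reads,
                prevalence_min_frac=thr.prevalence_min_frac,
                rho_min=thr.rho_min,
                q_max=thr.q_max,
                max_degree=thr.max_degree,
                relative_abundance=thr.relative_abundance,
                prevalence_denominator=thr.prevalence_denominator,
            )
            networks.append(net)
            network.write_edge_list(net, net_dir / f"{plate.plate_id}.edges.tsv")

        stage = "ensemble"
        prevalences = ensemble.pair_prevalence(networks)
        robust = ensemble.retain_robust_pairs(prevalences, fo_min=thr.fo_min)
        top = ensemble.top_pairs_report(prevalences, k=thr.k_top)
        jac = ensemble.jaccard_matrix(networks)
        n_unique = ensemble.unique_pair_count(networks)
        ensemble.write_pair_report(prevalences, outdir / "pair_prevalence.tsv")
        ensemble.write_pair_report(robust, outdir / "robust_pairs.tsv")
        top.to_csv(outdir / "top_pairs.tsv", sep="\t", index=False)

        planted_recall = {}
        robust_by_group: dict[tuple[str, str], set[frozenset]] = {}
        for p in robust:
            robust_by_group.setdefault(p.group, set()).add(frozenset((p.zotu_a, p.zotu_b)))
        for sample_type, truth in truths.items():
            for medium in config.simulator.media:
                got = robust_by_group.get((sample_type, medium), set())
                planted = truth.pair_keys
                recall = (len(planted & got) / len(planted)) if planted else float("nan")
                planted_recall[f"{sample_type}/{medium}"] = recall

        stage = "match"
        match_ss = np.random.SeedSequence((config.seed, 7))
        zotu_seqs = {}
        for sample_type, source in sorted(sources.items()):
            zotu_seqs.update(
                synthetic.simulate_zotu_sequences(source.species_ids, seed=_spawn_seed(match_ss))
            )
        isolates, isolate_truth = synthetic.simulate_isolate_sequences(
            zotu_seqs,
            n_isolates_per_zotu=config.matching.n_isolates_per_zotu,
            n_unrelated=config.matching.n_unrelated_isolates,
            mutation_rate=config.matching.isolate_mutation_rate,
            seed=_spawn_seed(match_ss),
            fwd_primer=config.matching.fwd_primer,
            rev_primer=config.matching.rev_primer,
        )
        tables.write_fasta(zotu_seqs, outdir / "zotu_v4.fasta")
        tables.write_fasta(isolates, outdir / "isolates_16s.fasta")
        # restrict matching to zotus appearing in any robust pair, as isolation
        # targets wells rich in the prevalent taxa
        target_zotus = sorted({z for p in robust for z in (p.zotu_a, p.zotu_b)})
        matches = []
        combos: dict[str, list[tuple[str, str]]] = {}
        if target_zotus:
            iso_v4 = {}
            for name, seq in isolates.items():
                try:
                    iso_v4[name] = matching.extract_v4(
                        seq,
                        fwd_primer=config.matching.fwd_primer,
                        rev_primer=config.matching.rev_primer,
                        max_mismatch=config.matching.max_mismatch,
                    )
                except matching.NoAmpliconError:
                    logger.warning("match: no amplicon for isolate %s", name)
            matches = matching.match_isolates(
                {z: zotu_seqs[z] for z in target_zotus},
                iso_v4,
                identity_threshold=config.matching.identity_threshold,
                distance_cap=config.matching.distance_cap,
            )
            matching.write_matches(matches, outdir / "isolate_matches.tsv")
            for p in robust:
                try:
                    combos[f"{p.zotu_a}-{p.zotu_b}"] = matching.enumerate_combinations(
                        (p.zotu_a, p.zotu_b), matches
                    )
                except ValueError:
                    combos[f"{p.zotu_a}-{p.zotu_b}"] = []

        stage = "assay"
        assay_ss = np.random.SeedSequence((config.seed, 11))
        rng = np.random.default_rng(_spawn_seed(assay_ss))
        calls = []
        assay_truth = []
        for pair_name, pair_combos in sorted(combos.items()):
            for iso_a, iso_b in pair_combos:
                true_label = str(rng.choice(synthetic.INTERACTION_LABELS))
                curves = synthetic.simulate_growth_curves(
                    true_label, noise_sd=config.assay.noise_sd, seed=_spawn_seed(assay_ss)
                )
                call = assay.classify_interaction(
                    curves,
                    windows=config.assay.windows,
                    epsilon=config.assay.epsilon,
                    pair_id=f"{pair_name}:{iso_a}+{iso_b}",
                )[0]
                calls.append(call)
                assay_truth.append(true_label)
        if calls:
            assay.write_calls(calls, outdir / "interaction_calls.tsv")

        stage = "report"
        report = {
            "config": config.model_dump(),
            "n_plates": len(plates),
            "n_effective_plates": len(effective),
            "effective_plate_ids": sorted(p.plate_id for p in effective),
            "n_networks": len(networks),
            "network_summaries": {
                net.plate_id: network.summarize(net).__dict__ for net in networks
            },
            "unique_pairs": n_unique,
            "n_robust_pairs": len(robust),
            "robust_pairs": [
                {"group": list(p.group), "pair": [p.zotu_a, p.zotu_b], "Np": p.np_count,
                 "Ng": p.ng_total, "FO": p.fo, "sign": p.sign_consensus}
                for p in robust
            ],
            "planted_pairs": {
                s: [[a, b] for a, b, _, _ in t.pairs] for s, t in truths.items()
            },
            "planted_recall": planted_recall,
            "jaccard_network_ids": list(jac.network_ids),
            "jaccard_mean_offdiag": float(
                np.mean(jac.values[~np.eye(len(jac.network_ids), dtype=bool)])
            ) if len(jac.network_ids) > 1 else 0.0,
            "n_matched_isolates": sum(1 for m in matches if m.matched),
            "n_isolates": len(isolates),
            "combinations": {k: [list(c) for c in v] for k, v in combos.items()},
            "interaction_calls": [
                {"pair": c.pair_id, "label": c.label, "true_label": t,
                 "effects": [c.effect_a, c.effect_b]}
                for c, t in zip(calls, assay_truth)
            ],
            "assay_accuracy": (
                sum(c.label == t for c, t in zip(calls, assay_truth)) / len(calls)
                if calls else None
            ),
        }
        report_path = outdir / "report.json"
        report_path.write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return RunReport(
        outdir=outdir,
        n_plates=len(plates),
        n_effective=len(effective),
        n_networks=len(networks),
        unique_pairs=n_unique,
        n_robust_pairs=len(robust),
        planted_recall=planted_recall,
        report_path=report_path,
    )
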