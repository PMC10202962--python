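# atacircle

Reconstruction of extrachromosomal circular DNA (ecDNA) from regular
paired-end ATAC-seq alignments.

ecDNA lacks the higher-order chromatin compaction of chromosomes, so its
source regions show strongly elevated ATAC-seq depth ("local depth"), and the
circular junctions leave discordant read pairs and clipped reads behind.
`atacircle` turns those signals into candidate circle structures:

1. **Read filtering/classification** — keep primary, non-duplicate reads
   with MAPQ > 10 outside a blacklist; classify reads as concordant,
   discordant (|insert| > 1500 bp or mates on different contigs) and/or
   clipped.
2. **Enrichment calling** — per-base Poisson tests against the genome-wide
   mean depth call *consecutive enrichment regions* (merged below 12.5 kb);
   a second Poisson test on the per-base discordant/total depth ratio
   (score cutoff 1.301 = −log10 0.05) calls *discordant-pair enrichment
   regions*, each assigned a junction side by strand vote.
3. **Breakpoint graph** — a multigraph whose nodes are discordant regions;
   *discordant* edges link regions sharing enough same-orientation read
   pairs, *consecutive* edges link facing left/right nodes inside one
   consecutive region and carry the retained DNA segment.
4. **Bayesian breakpoint refinement** — a uniform ("German-tank") model on
   discordant read ends combined with a normal model on clipped-read ends;
   grid search gives the MLE and 95% credible interval per node.
5. **Circle search** — a depth-first search for simple cycles whose edges
   strictly alternate between the two types, largest/deepest segments
   first, deduplicated under rotation/reflection and capped (default 1000);
   report filters: fold enrichment > 10, junction support > 2, repeat
   overlap < 5%.

A **simulator** (multi-segment circular templates, wrap-around fragments,
uniform linear background, and a "perfect aligner" that soft-clips
junction-crossing reads) and an **evaluator** (coverage+structure and
breakpoint-CI+structure match criteria, precision/recall/F1) make the whole
pipeline testable offline.

## CLI

```bash
# call candidate circles from a coordinate-sorted BAM/SAM
atacircle detect sample.bam --blacklist blacklist.bed --out-dir out/
# -> out/candidates.bed (one row per segment, with breakpoint CI columns),
#    out/candidates.json, out/config.json

# simulate a mock-ecDNA sample (SAM + truth JSON)
atacircle simulate --seed 1 --n-ecdna 5 --local-depth 30 --out-dir sim/

# score predictions against simulated truth
atacircle evaluate out/candidates.json sim/truth.json --out-dir eval/

# simulate + detect + evaluate in one in-memory pass
atacircle bench --seed 1 --n-samples 5 --read-len 100
```

All commands accept `--config file` with plain `key = value` lines mirroring
the `PipelineConfig` fields; unknown keys are rejected and the resolved
configuration is echoed as JSON next to every output.

## Output BED dialect

Tab-separated, 0-based half-open, one row per circle segment:

```
chrom  start  end  name=circleID_segIndex_of_N  score=junction_support(<=1000)
strand  ci_start_low  ci_start_high  ci_end_low  ci_end_high
```

## Limitations

Circles containing repeated or foldback segments (HSR/BFB-like focal
amplifications) cannot be reconstructed without copy-number information;
node revisits are deliberately prohibited in the cycle search.
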