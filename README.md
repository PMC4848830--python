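# imirp

**imirp** designs mutant 3'UTR sequences in which chosen microRNA target
sites are disrupted *without creating new ones*. It is aimed at
experimentalists building luciferase/GFP reporter constructs or mutant
UTRs for miRNA-target validation: mutating a seed match is easy; mutating
it without accidentally writing a fresh seed match for one of the
hundreds of other miRNAs expressed in the same species is the part a
computer should do.

## The problem and the model

A miRNA recognizes its targets mainly through its **seed** — nucleotides
1–8 at the miRNA 5' end. imirp scans the mRNA with an 8-nt sliding
window (window position *w<sub>k</sub>* pairs antiparallel with miRNA
position *9−k*) and classifies five canonical site types:

| type | definition |
|---|---|
| 6mer | w2..w7 complementary to miRNA 2–7 |
| 7mer-A1 | 6mer with an A at w8 (opposite miRNA position 1) |
| 7mer-m8 | w1..w7 complementary to miRNA 2–8 |
| 8mer | 7mer-m8 with an A at w8 |
| OS-6mer | offset 6mer: w1..w6 complementary to miRNA 3–8 |

Optionally a single G:U wobble may substitute for one Watson–Crick pair.
The predictor is deliberately complementarity-only (over-predicting):
its job is to flag any motif with the *potential* to be functional.

Mutagenesis is constrained to the 6-nt **core** complementary to miRNA
positions 2–7 (the span `[anchor, anchor+5]`, where the anchor is the
position opposite miRNA position 7). By default each site receives
exactly two *adjacent* substitutions drawn from a user-chosen base set —
enough to abolish repression while keeping the altered surface, and
hence the space of possible new sites, small. Sites separated by fewer
than 7 intact nucleotides are merged into a *mutationally independent
region* (no 8-nt window can straddle two regions separated by ≥ 7 nt),
and each region is solved separately: candidates are generated, the full
mutant is re-predicted, sites present in the mutant but absent from the
input — keyed by (miRNA, position) — are the **illegitimate** set, and a
candidate survives only if none of its illegitimate sites falls in a
banned (site type, wobble class) combination. The search stops at five
valid mutants per region or exhaustion of the space.

## Worked example

A 60-nt sequence carrying an 8mer site for hsa-miR-7-5p (seed
`UGGAAGAC`) at window 20–27; the core anchor (position opposite miRNA
position 7) is 21:

```
$ imirp predict --sequence utr.fa --mirna-fasta mature.fa --species hsa
mirna_id,accession,site_type,window_start,window_end,gu_used,gu_position
hsa-miR-7-5p,MIMAT0000252,8mer,20,27,False,

$ imirp count --sequence utr.fa --site 21
region 1 [21-26], 1 site(s): 45 candidate mutant(s)

$ imirp run --sequence utr.fa --mirna-fasta mature.fa --species hsa \
        --site 21 --seed 7 --out out
region 1 [21-26]: solved, 5 mutant(s) displayed, 5 candidate(s) examined
assembled mutant written to out/project_info.txt
```

The 45 candidates are the 5 adjacent two-base runs of the core × 3
replacement choices per position. `out/project_info.txt` records the
assembled mutant:

```
input sequence:
CGATTCAAATGACGGCAGCGTCTTCCAAGTCCCTGAGAGGCTTGTTCCGGAAATGTGCCA

assembled mutant sequence:
CGATTCAAATGACGGCAGCGTCTTGGAAGTCCCTGAGAGGCTTGTTCCGGAAATGTGCCA
```

Two adjacent changes (CC→GG at positions 25–26) sit inside the core, the
miR-7 site is gone from `mutant_predictions.csv`, and `new_sites.csv` is
empty — no illegitimate 8mer/7mer-m8/7mer-A1 was created for any hsa
miRNA in the database. A nonzero exit (with the regions named) means
some region's space was exhausted and a different strategy — more
changes, a different base set — is needed.

The same workflow is available as a library (`run_project`,
`predict_sites`, `count_mutation_space`, ...), and `imirp.fixtures`
generates fully synthetic, predictor-screened projects (random miRNA
databases, planted sites of every type, adversarial "trap" miRNAs) for
testing without any downloads.

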