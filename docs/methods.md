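# Methods

`wgsflow` is a hybrid agent-based / discrete-event systems model of the
diagnostic pathway for newly diagnosed stage IV non-small-cell lung cancer
(NSCLC) patients in a national healthcare system in which whole genome
sequencing (WGS) is being introduced as a last-resort biomarker test.  This
note records the model, its parameterization, the calibrations behind the
defaults, and the limits of what the synthetic world can show.

## Model structure

**Agents.** Hospitals (43 general, 21 teaching, 8 academic), one national
WGS facility, 7 molecular tumor boards (MTBs, each hosted by an academic
hospital; the eighth academic hospital uses its nearest neighbour's board),
and patient agents arriving as a homogeneous Poisson process at 5313 per
year.  Each replication runs for 2000 days (~29,000 patients) by default.

**Pathway.** A patient enters a home hospital drawn with probability equal to
the hospital's catchment weight.  The hospital runs its standard-of-care
(SoC) panel in parallel (panel turnaround = slowest assay): general hospitals
run ALK IHC plus EGFR/KRAS Sanger; teaching and academic hospitals run PD-L1
and ALK IHC plus a targeted gene panel (EGFR, ROS1, BRAF, KRAS).  A covered
positive marker ends the pathway with a treatment recommendation.
SoC-negative patients cascade general → teaching → academic, each hop
realized with the scenario's referral percentage and adding a
Uniform(4, 8)-day transfer delay.  At an academic hospital WGS is the last
resort, gated by pathologist adoption AND patient preference (independent
Bernoulli gates); gate failure concludes the pathway without a biomarker.
On the WGS route a fresh-frozen biopsy is taken, ships to the facility in 3
days, occupies one sequencing slot for the full 14-calendar-day (10
working-day) processing duration, and, if its tumor-cell content reaches
20%, produces a report that the hospital's MTB discusses at its next
eligible meeting — the discussion is the treatment recommendation.  Death
competes with every stage: an exponential time-to-death (mean 216 days,
median ≈ 150 days) is drawn at diagnosis, and a patient who dies before a
recommendation concludes with reason `died`.

**Event kernel.** A binary-heap event queue dispatches events in
nondecreasing time, ties broken by priority (death outranks pathway
progress) then FIFO.  Randomness is split into named substreams (arrivals,
profiles, geography, behavior, biopsy, delays, mortality), each seeded from
`(master seed, replication index, stream label)`, so a replication is a pure
function of scenario, seed and index, and sweeps can share arrival and
profile draws across parameter values (common random numbers).

## Parameters and calibration

Tunable parameters live in `ScenarioConfig` (YAML/JSON).  The key defaults:

| parameter | default | basis |
|---|---|---|
| hospitals per stratum | 43 / 21 / 8 | national landscape |
| annual patients | 5313 / yr | national incidence of the indication |
| WGS cost | €2925 | current price per sequenced patient |
| SoC assay costs | €70–400 | current SoC price range |
| sequencing duration | 14 calendar d (10 working d) | facility turnaround |
| tumor-cell threshold | ≥ 20% | sequencing success requirement |
| tumor-cell distribution | Beta(1.2121, 2.0) on [0, 100] | calibrated: P(< 20%) = 0.280 |
| assay turnarounds | IHC 7 d, Sanger 10 d, TGP 12 d | calibrated (see below) |
| referral delay | Uniform(4, 8) d | "several days" per transfer; calibrated jointly |
| biopsy logistics | 3 d | acquisition + shipping, fixed |
| adoption, preference | 0.90 × 0.90 | calibrated demand gates (see below) |
| marker prevalences | KRAS .30, EGFR .12, ALK .04, ROS1 .02, BRAF .03, PD-L1-high .28, WGS-only .08 | plausible NSCLC values; P(no SoC marker) ≈ 0.405 |
| mean survival | 216 d (exponential) | median ≈ 150 d untreated stage IV |
| MTB interval / cutoff / deferral | 7 d / 2 d / 0.5 | calibrated (see below) |

Working days convert to calendar days at 7/5 throughout.

**Why these calibrations.** Three aggregate behaviors pin down parameters
that are not individually observable:

1. *Biopsy suitability.* The Beta shape `a` was solved (with `b = 2`) so the
   probability mass below the 20% tumor-cell threshold is exactly 0.280;
   about 28% of biopsies fail sequencing.
2. *Referral effect.* Panel turnarounds and the referral delay were jointly
   chosen so the mean pathway duration with all SoC-negative patients
   referred is about twice the duration with none referred (the model's
   referral mechanism must produce a two-fold spread).  With IHC 7 / Sanger
   10 / TGP 12 days and Uniform(4, 8)-day delays the simulated ratio is
   ≈ 2.1, with death truncation included.
3. *Sequencing demand.* The behavioral gates were set to 0.90 × 0.90 so that
   annual biopsy arrivals at the facility land between 1450 and 1600 per
   year (measured ≈ 1470–1500 after death attrition en route and the
   end-of-horizon edge).  In this regime a capacity of 1600 biopsies/yr is
   just sufficient (queue utilization ≈ 0.95), 1450 is mildly unstable, and
   1300 is extreme undercapacity — the qualitative ordering the capacity
   experiment explores.

**Capacity mechanism.** Annual capacity `c` becomes
`floor(c × duration / 365)` concurrent processing slots (≥ 1); a FIFO queue
forms when all slots are busy.  Every *shipped* biopsy occupies a slot for
the full duration: tumor-cell QC happens inside the facility pipeline, so
unsuitable samples consume throughput like any other, but only suitable
(sequenced) samples are billed the WGS price and generate an MTB report.
This makes "biopsies annually" the natural unit of the facility's load.

**MTB waiting time.** With meetings every `m` days, an agenda cutoff `c`
days before the meeting and deferral probability `p`, reports arriving
uniformly over the meeting cycle wait `m/2 + c + p·m` days in expectation
(closed form, used as the test oracle).  The defaults (7, 2, 0.5) give 9
days; biweekly meetings give 16 days — a difference of ≈ 7 days.  The
deferral mechanism is a deliberately simple stand-in for crowded agendas and
incomplete dossiers; the 0.5 default is calibrated so the weekly→biweekly
shift is ≈ 7 days rather than the naive half-interval 3.5.

## The synthetic world vs. reality

The generator emulates: stratified provider heterogeneity with heavy-tailed
catchment volumes (Dirichlet weights with academic 3× / teaching 2× /
general 1× concentration), per-replication random geography on the unit
square (so referral trees vary across runs while the nearest-hospital rule
is constant), parallel in-house SoC testing, last-resort WGS with behavioral
gates, a capacitated central facility, and periodic batch interpretation by
MTBs.

It does not emulate: real hospital identities, geography or travel times;
assay sensitivity below 1.0 (a "missed" biomarker is a profile property, not
an assay error); re-biopsy after an unsuitable sample (one attempt, then the
pathway concludes on SoC evidence); adoption diffusion over time (gates are
static); treatment choice or outcomes beyond the recommendation; repeat
testing at progression.  Passing tests therefore demonstrate the internal
mechanics and the calibrated aggregate regimes, not forecasts for any real
system.

## Numerical and design choices

- **Time** is a continuous day scale; no slotting.  Events tied in time
  dispatch by priority (death first), then insertion order.
- **Truncation.** Patients still in the pathway at the 2000-day horizon are
  excluded from duration/cost statistics (≈ 1% of patients at defaults);
  they are counted in the conservation identity generated = concluded +
  died + in-progress, which is asserted after every replication.
- **Warm-up** defaults to 0 days (configurable): the long horizon dominates
  any initial transient, and the landscape is built before the first
  arrival, so there is no empty-system bias beyond the facility queue.
- **Tie-breaks.** Nearest-hospital ties go to the lowest hospital index;
  MTB meeting-boundary arithmetic uses a 1e-12 tolerance so a report landing
  exactly at the cutoff boundary makes that meeting.
- **Degenerate inputs.** Horizon 0 yields an empty, valid replication;
  empty statistics are NaN-marked rather than raised; an empty panel, a
  missing next-stratum hospital, or more MTBs than academic hosts are
  configuration errors.
- **Experiment scale.** The preset experiments default to 500 replications;
  the bundled acceptance computations use 20 replications of the full
  2000-day horizon, which, with common random numbers, is enough to resolve
  the compared means to well under the decision tolerances.

## Known limitations

- The deferral model of MTB congestion is phenomenological; an explicit
  per-case workload model could replace it without structural change.
- Unsuitable biopsies occupying a full processing slot is a simplification;
  if QC rejected them early, the same demand regimes would require slightly
  stronger gates or prevalences.
- Mean cost per patient depends on the SoC repeat-testing assumption
  (referred patients are re-paneled at each hospital); alternative
  assumptions shift its level but not the cost-sweep slopes.
- The exponential survival model is memoryless by construction; real
  survival curves with a shoulder would lower the death-before-
  recommendation share at short durations.
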