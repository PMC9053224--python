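{
 "config": {
  "assoc": {
   "family": "per_drug_10",
   "pairs": [
    {
     "side_effect": "weight_gain",
     "trait": "bmi"
    },
    {
     "side_effect": "insomnia",
     "trait": "insomnia"
    }
   ]
  },
  "cooccurrence": {
   "effects": [
    "nausea",
    "headache",
    "sweating",
    "weight_gain"
   ],
   "min_pair_n": 30
  },
  "descriptives": {
   "stratify_sex": true
  },
  "prs": {
   "clump_kb": 10000,
   "clump_r2": 0.1,
   "pcs_k": 10
  },
  "seed": 7,
  "sem": {
   "nodes": 9,
   "side_effects": [
    "nausea",
    "sweating"
   ],
   "starts": 2
  },
  "simulate": {
   "block_rho": 0.5,
   "class_loadings": {
    "sweating": {
     "SNRI": 0.45
    }
   },
   "emit_indication_flag": true,
   "exposure_probs": {
    "amitriptyline": 0.3,
    "citalopram": 0.35,
    "desvenlafaxine": 0.3,
    "duloxetine": 0.3,
    "escitalopram": 0.45,
    "fluoxetine": 0.4,
    "mirtazapine": 0.3,
    "paroxetine": 0.25,
    "sertraline": 0.55,
    "venlafaxine": 0.45
   },
   "genetic_betas": {
    "insomnia": [
     "insomnia",
     0.25
    ],
    "weight_gain": [
     "bmi",
     0.3
    ]
   },
   "gwas_n": 50000,
   "indication_prob": 0.3,
   "n_blocks": 8,
   "n_participants": 400,
   "n_variants": 80,
   "sex_effects": {
    "nausea": 0.3
   }
  },
  "stages": [
   "simulate",
   "descriptives",
   "cooccurrence",
   "sem",
   "prs",
   "assoc"
  ]
 },
 "outputs": {
  "assoc.tsv": "51a651c7e0937e2cd3d924f8e8bde2b99db103855425f9c727a3e96e7ef97682",
  "linkage.tsv": "e938e4aa705c44229a64704d09303df32bc78d21a71c36ee1cff62a637e8653c",
  "medians.json": "65e31dcb47661be4200f642e0b395832d66d26ff13216b733ba882ccee3e01ff",
  "pcs.tsv": "21b1354eeaa73c02493c82062ab6eaed93d7e3afa008d58b42de27b4b5b7d35e",
  "prevalence.tsv": "cee4d8619f9c88f907435d274ff61128f4ef51aaef046a5d72ad191c7b672c5d",
  "prs.tsv": "3c233025f21a7f51e621d0689a7c3dc5ded045927acd396c5a13831da3276c58",
  "prs_log.json": "783ac696aa5d068be3407977c080accc3cdda98679da179c6a6a7f8ad07ba332",
  "rho.tsv": "fdddd4e66c10265e0ec959fb8450f8b97ec3cba620cdfdacc8a0d4cd9b33d69b",
  "sem_comparisons.tsv": "0a45461c962f1e68f6899c0031c09a31fbcd872dfa0c20704ea3cdfb4b40e97b",
  "sem_loadings.tsv": "bc9c08d7f359d2a549c86be11e31a9ce50e9b7845a0126b8a4f1df1e655a88eb",
  "sim/dosages.tsv": "fbc02687f132ab86cae073c3f582dff4f976245c3755378e87b1b8ad174bed6f",
  "sim/phenotypes.tsv": "f687951c9d56df367cc650113e43a5cb48fd6a87a2b6c4ba32dd996038d48737",
  "sim/sumstats_bmi.tsv": "e3f23fab76fa9437d081b5e314903b1fbd0c0a214fac5509a159edea2bfa1d9d",
  "sim/sumstats_insomnia.tsv": "c0c398d183b099cf695a51693ceee2442991348767b3f23c89f398f9d1e943de",
  "sim/variants.tsv": "cb5f164c4fa01ad326c9dbee53f2415af8c34a157f5d39b58aaf628c53c79d9d",
  "tests.tsv": "8aa9963332ec1a71ed7c9281005d00f9aeeaf658c5cbc941f643266999ac901f"
 },
 "seed": 7,
 "stages_run": [
  "simulate",
  "descriptives",
  "cooccurrence",
  "sem",
  "prs",
  "assoc"
 ],
 "versions": {
  "numpy": "2.4.6",
  "pandas": "2.3.3",
  "sidefx": "0.1.0"
 }
}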