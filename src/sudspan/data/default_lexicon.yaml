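# Default category lexicons, reconstructed from in-text diagnosis examples
# (clinical abbreviations such as "etoh", "mj", "ud", "use d/o", checkbox
# criteria blocks) plus the DSM-5 category names.  Users may replace this file;
# see load_lexicons().
#
# "substance use disorder" is shared across every category because
# checkbox-style diagnoses ("meets criteria for substance use disorder:
# cocaine [] mild ...") name the substance only *after* the generic
# use-disorder phrase.
shared_substance_terms:
  - substance use disorder

categories:
  alcohol:
    substance_terms: [alcohol, etoh, alcoholism, alcoholic, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: &severity
      - mild
      - moderate
      - mod/severe
      - mod
      - severe
      - sever
      - in sustained remission
      - in early remission
      - in remission
      - severity unspecified
      - unspecified
      - continuous use
    proxy_ground_truth: alcohol use disorder/dependence
  opioid:
    substance_terms: [opioid, opiate, heroin, kratom, vicodin, oxycodone, fentanyl, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: opioid use disorder/dependence
  cannabis:
    substance_terms: [cannabis, marijuana, mj, thc, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud, user]
    severity_terms: *severity
    proxy_ground_truth: cannabis use disorder/dependence
  sedative_hypnotic_anxiolytic:
    substance_terms: [sedative, hypnotic, anxiolytic, benzodiazepine, xanax, valium, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: sedative use disorder/dependence
  cocaine:
    substance_terms: [cocaine, crack, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: cocaine use disorder/dependence
  amphetamine:
    substance_terms: [amphetamine, methamphetamine, stimulant, meth, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: amphetamine use disorder/dependence
  caffeine:
    substance_terms: [caffeine, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: caffeine use disorder/dependence
  hallucinogen:
    substance_terms: [hallucinogen, mdma, ecstasy, lsd, psilocybin, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: hallucinogen use disorder/dependence
  nicotine:
    substance_terms: [nicotine, tobacco, cigarette, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: nicotine use disorder/dependence
  inhalant:
    substance_terms: [inhalant, nitrous oxide, glue, solvent, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: inhalant use disorder/dependence
  other_psychoactive:
    substance_terms: [other psychoactive, other/unknown substance, substance, coricidin, substance use disorder]
    disorder_terms: [use disorder, use d/o, use do, use dis, dependence, disorder, ud, sud]
    severity_terms: *severity
    proxy_ground_truth: other psychoactive substance use disorder/dependence
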