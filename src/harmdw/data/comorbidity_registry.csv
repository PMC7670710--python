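name,group,n_estimates_a,comorbid_pct_a,comorbid_ci_low,comorbid_ci_high,n_estimates_b,comorbid_pct_b,community_pct,community_se,community_ci_low,community_ci_high,dw_levels,source_key,rr_printed,se_printed
Any DSM-IV Axis 1 disorder,other,5,74.8,36.5,93.9,,,20.0,,18.9,21.0,,a,3.7,0.74
Any alcohol or substance use disorder,substance,10,22.2,16.1,29.8,3,57.5,5.1,,4.5,5.8,,a,7.8,0.85
Any alcohol use disorder,substance,12,21.2,5.6,28.1,8,28.1,8.5,0.24,,,Very mild:0.123;Mild:0.235;Moderate:0.373;Severe:0.570,a,2.9,0.68
Alcohol abuse,substance,9,18.2,13.4,24.2,,,4.7,0.18,,,,a,3.9,0.60
Alcohol dependence,substance,7,15.2,10.2,22.0,,,3.8,0.14,,,,a,4.0,0.81
Any substance (non-alcohol) use disorder,substance,7,7.0,1.7,24.9,3,17.2,2.0,1.00,,,,a,6.1,4.23
Substance (non-alcohol) abuse,substance,8,6.6,3.3,12.7,,,1.4,0.08,,,,a,4.7,1.73
Substance (non-alcohol) dependence,substance,6,4.2,1.5,11.4,,,0.6,0.05,,,,a,7.0,4.25
Nicotine dependence,substance,3,56.4,35.7,75.2,4,60.1,12.8,0.39,,,,a,4.6,0.80
Cannabis use disorder,substance,3,11.5,4.8,25.0,,,1.5,0.08,,,Mild dependence:0.329;Moderate to severe:0.479,a,7.7,3.46
Any mood disorder,mood,10,23.1,14.9,34.0,3,37.9,9.2,0.22,,,,a,3.3,0.54
Major depressive disorder,mood,17,29.9,20.5,41.3,6,23.1,7.1,0.20,,,Mild:0.145;Moderate:0.396;Severe:0.658,a,3.7,0.75
Dysthymic disorder,mood,3,6.7,4.8,9.2,,,1.8,0.09,,,range:0.33-0.38,a,3.7,0.65
Bipolar disorder,mood,10,8.8,4.4,17.1,6,9.8,1.7,0.08,,,Manic episode:0.492;Residual state:0.032,a,5.5,1.92
Any anxiety disorder,anxiety,10,17.6,10.8,27.3,3,37.4,11.1,0.33,,,Mild:0.030;Moderate:0.133;Severe:0.523,a,2.5,0.39
Obsessive compulsive disorder (OCD),anxiety,7,8.2,3.4,18.6,,,1.2,0.30,,,range:0.12-0.60,a,6.8,3.66
Panic disorder,anxiety,6,13.7,6.7,26.0,,,1.5,0.07,,,range:0.11-0.69,a,9.1,3.31
Generalised anxiety disorder (GAD),anxiety,4,14.4,3.9,40.8,3,11.1,2.1,0.10,,,range:0.17-0.60,a,6.1,4.49
Post-traumatic stress disorder (PTSD),anxiety,4,12.3,3.4,35.7,,,4.7,0.17,,,range:0.11-0.51,a,2.6,1.76
Social phobia,anxiety,3,14.9,2.0,59.8,,,2.8,0.13,,,range:0.17-0.59,a,5.3,5.27
Intermittent explosive disorder,other,3,4.6,2.5,8.4,,,3.9,0.30,,,,a,1.2,0.40
Kleptomania,other,3,2.7,1.2,5.9,,,0.4,,0.1,1.0,,a,6.8,4.90
Psychotic disorder,other,5,4.7,3.4,6.5,,,0.4,0.1,,,Acute state:0.778;Residual state:0.588,a,11.8,3.54
Somatoform disorder,other,5,3.6,1.6,8.0,,,0.8,,0.3,1.4,all:0.144,a,4.5,2.58
Adjustment disorder,other,5,9.2,4.8,17.2,,,0.3,,0.1,0.5,,a,30.7,14.83
ADHD,other,4,9.3,4.1,19.6,,,4.4,0.6,,,all:0.045,a,2.1,0.94
Any personality disorder (PD),personality,9,47.9,29.8,66.7,,,7.8,,6.1,9.5,,c,6.1,1.39
Any cluster A disorder,personality,4,6.1,1.5,22.1,,,3.8,,3.2,4.4,,c,1.6,1.39
Paranoid personality disorder,personality,8,10.1,4.2,22.1,,,2.3,,1.6,3.1,,c,4.4,2.12
Schizoid personality disorder,personality,8,6.0,2.5,13.7,,,1.1,,0.7,1.5,,c,5.5,2.79
Schizotypal personality disorder,personality,7,4.1,0.8,19.4,,,0.8,,0.5,1.1,,c,5.1,6.01
Any cluster B disorder,personality,4,17.6,6.0,41.8,,,2.8,,1.8,3.7,,c,6.3,3.44
Antisocial personality disorder,personality,14,14.0,10.5,18.4,2,28.8,1.4,,0.8,2.3,,c,15.3,4.42
Borderline personality disorder,personality,8,13.1,4.3,33.5,,,1.8,,1.2,2.5,all:0.193,c,7.3,4.35
Histrionic personality disorder,personality,7,6.3,1.0,30.4,,,0.6,,0.4,0.9,,c,10.5,12.7
Narcissistic personality disorder,personality,8,16.6,8.0,31.2,,,1.9,,0.1,5.6,,c,8.7,7.16
Any cluster C disorder,personality,4,12.6,4.8,29.1,,,5.0,,4.2,5.9,,c,2.5,1.26
Avoidant personality disorder,personality,6,13.4,5.9,27.5,,,2.7,,1.9,3.7,,c,5.0,2.21
Dependent personality disorder,personality,8,6.0,1.4,22.5,,,0.8,,0.5,1.3,,c,7.5,7.00
Obsessive-compulsive personality disorder,personality,6,13.4,5.9,27.5,,,3.2,,2.4,4.1,,c,4.2,1.81
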