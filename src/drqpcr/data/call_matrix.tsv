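gene_id	tissue	dir_tol_2h	dir_tol_5h	dir_sens_2h	dir_sens_5h	pattern_tolerant	pattern_sensitive	contrast_control_2h	contrast_control_5h	contrast_stress_2h	contrast_stress_5h	ambiguous
CaNAC02	root	down	down	down	down	down	down	lower	lower	lower	lower	stress_2h
CaNAC04	root	none	none	down	down	unchanged	down	similar	higher	higher	higher	stress_2h
CaNAC05	root	none	none	none	none	unchanged	unchanged	similar	similar	similar	similar	-
CaNAC06	root	up	up	up	up	up	up	lower	lower	lower	lower	stress_2h
CaNAC16	root	up	up	up	up	up	up	higher	higher	higher	higher	stress_2h
CaNAC19	root	up	up	up	up	up	up	similar	similar	similar	similar	-
CaNAC21	root	none	none	none	none	unchanged	unchanged	similar	similar	similar	similar	-
CaNAC24	root	up	up	up	up	up	up	higher	similar	higher	higher	stress_2h
CaNAC27	root	up	up	none	up	up	up	lower	lower	lower	higher	stress_2h
CaNAC40	root	up	up	up	up	up	up	lower	lower	similar	similar	-
CaNAC41	root	none	none	none	none	unchanged	unchanged	similar	similar	similar	similar	-
CaNAC43	root	up	up	none	up	up	up	lower	lower	lower	similar	stress_2h
CaNAC44	root	none	none	none	up	unchanged	up	similar	similar	similar	similar	-
CaNAC46	root	none	down	none	down	down	down	similar	similar	similar	similar	-
CaNAC47	root	up	up	none	none	up	unchanged	lower	lower	similar	similar	-
CaNAC50	root	up	up	up	up	up	up	lower	lower	lower	lower	stress_2h
CaNAC52	root	up	up	none	up	up	up	similar	similar	similar	similar	-
CaNAC57	root	none	none	none	none	unchanged	unchanged	similar	similar	similar	similar	-
CaNAC67	root	up	up	up	up	up	up	similar	similar	similar	similar	-
CaNAC02	leaf	down	down	down	down	down	down	lower	lower	lower	lower	-
CaNAC04	leaf	none	down	down	down	down	down	similar	higher	higher	higher	-
CaNAC05	leaf	up	up	none	up	up	up	similar	similar	higher	similar	stress_5h
CaNAC06	leaf	up	up	up	up	up	up	lower	lower	similar	similar	stress_2h,stress_5h
CaNAC16	leaf	up	up	none	up	up	up	higher	higher	higher	higher	-
CaNAC19	leaf	up	up	up	up	up	up	similar	lower	similar	similar	stress_2h,stress_5h
CaNAC21	leaf	up	up	none	up	up	up	similar	similar	similar	similar	stress_2h,stress_5h
CaNAC24	leaf	down	up	down	none	mixed	down	similar	similar	similar	similar	stress_2h,stress_5h
CaNAC27	leaf	up	up	none	up	up	up	lower	lower	similar	similar	stress_2h,stress_5h
CaNAC40	leaf	up	up	none	up	up	up	lower	lower	similar	similar	stress_2h,stress_5h
CaNAC41	leaf	up	up	none	up	up	up	similar	lower	similar	similar	stress_2h,stress_5h
CaNAC43	leaf	up	up	none	up	up	up	lower	lower	similar	similar	stress_2h,stress_5h
CaNAC44	leaf	up	up	none	none	up	unchanged	similar	lower	similar	similar	stress_2h,stress_5h
CaNAC46	leaf	up	none	none	down	up	down	lower	similar	similar	similar	stress_2h,stress_5h
CaNAC47	leaf	up	up	up	none	up	up	lower	similar	similar	similar	stress_2h,stress_5h
CaNAC50	leaf	up	up	up	up	up	up	lower	lower	similar	similar	stress_2h,stress_5h
CaNAC52	leaf	up	up	none	up	up	up	similar	similar	similar	similar	stress_2h,stress_5h
CaNAC57	leaf	up	up	up	up	up	up	similar	similar	similar	similar	stress_2h,stress_5h
CaNAC67	leaf	up	up	up	up	up	up	lower	similar	similar	similar	stress_2h,stress_5h
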